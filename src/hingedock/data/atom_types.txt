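# hingedock atom-type parameter table
#
# One row per force-field atom type.  Whitespace-delimited columns:
#
#   type     type code (key used by AtomRecord.type_code)
#   elem     chemical element symbol
#   Rii      like-pair van der Waals equilibrium distance, Angstrom
#   eps      van der Waals well depth, kcal/mol
#   hb       hydrogen-bond role of the type:
#              D  = donor heavy atom, A = acceptor, DA = both,
#              PH = polar hydrogen, -  = none
#   S        atomic solvation energy per unit volume, kcal/(mol*A^3)
#   V        fragmental atomic volume, A^3
#   Occmax   maximum occupancy, A^3
#
# The van der Waals Rii/eps values follow the AMBER-derived table used by
# classic empirical docking scoring functions.  The solvation parameters
# (S, V, Occmax) are documented PLACEHOLDER values, not a fitted set.  S
# acts as a dehydration penalty density: polar atoms carry the largest
# positive S, so a polar moiety raises the score (worsens it) in
# proportion to its remaining solvent-accessible occupancy, while carbon
# carries a small positive S (burial is mildly rewarded).  This realizes
# the term's purpose — stopping hydrophilic groups from looking better
# than they are — in cross-molecule rankings.  Occmax approximates the
# Gaussian-weighted neighbor volume of a fully buried atom at
# sigma = 3.5 A.  Edit freely: this file is the single source of truth
# and is expected to be replaced wholesale when a calibrated table
# becomes available.
#
# type    elem  Rii    eps     hb    S         V       Occmax
C.3       C     4.00   0.150   -     0.0008    12.77   350.0
C.2       C     4.00   0.150   -     0.0008    13.50   350.0
C.ar      C     4.00   0.150   -     0.0006    10.80   350.0
N.3       N     3.50   0.160   DA    0.0045    11.96   350.0
N.4       N     3.50   0.160   D     0.0090    11.00   350.0
N.ar      N     3.50   0.160   A     0.0040    12.00   350.0
N.am      N     3.50   0.160   D     0.0045    12.00   350.0
N.pl      N     3.50   0.160   D     0.0040    11.50   350.0
O.3       O     3.20   0.200   DA    0.0060    11.08   350.0
O.2       O     3.20   0.200   A     0.0065    10.80   350.0
O.co2     O     3.20   0.200   A     0.0090    10.50   350.0
S.3       S     4.00   0.200   A     0.0008    17.10   350.0
P.3       P     4.20   0.200   -     0.0025    15.00   350.0
H         H     2.00   0.020   -     0.0000    1.00    150.0
H.p       H     2.00   0.020   PH    0.0000    1.00    150.0
F         F     3.09   0.080   -     0.0004    9.00    350.0
Cl        Cl    4.09   0.276   -     0.0006    18.10   350.0
Br        Br    4.33   0.389   -     0.0007    21.30   350.0
I         I     4.72   0.550   -     0.0008    27.00   350.0
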