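"""Parameter handling for the binding free energy function.

Everything the score needs as *data* lives here: the five term weights,
per-type van der Waals parameters, the hydrogen-bond 12-10 well, the
angular directionality weight, the sigmoidal distance-dependent
dielectric, and the solvent-contact solvation table (S_i, V_i, Occ_max).

Weights and tables are deliberately configuration, not code: the
functional form of the score is fixed but every constant can be swapped
from a text table or overridden programmatically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path

import numpy as np

#: Coulomb conversion constant, kcal*Angstrom/(mol*e^2).
COULOMB_CONSTANT = 332.06

#: Receptor-ligand distance below which a pose is flagged as clashing, Angstrom.
HARD_CLASH_DISTANCE = 1.6


@dataclass(frozen=True)
class AtomTypeParams:
    """Per-type force-field parameters (one row of the text table)."""

    type_code: str
    element: str
    rii: float      # like-pair vdW equilibrium distance, A
    eps: float      # vdW well depth, kcal/mol
    hb: str         # 'D', 'A', 'DA', 'PH' or '-'
    s: float        # solvation energy per unit volume, kcal/(mol*A^3)
    v: float        # fragmental atomic volume, A^3
    occ_max: float  # maximum occupancy, A^3

    @property
    def is_donor(self) -> bool:
        return "D" in self.hb and self.hb != "-"

    @property
    def is_acceptor(self) -> bool:
        return "A" in self.hb

    @property
    def is_polar_h(self) -> bool:
        return self.hb == "PH"


@dataclass(frozen=True)
class Weights:
    """Dimensionless term weights W of the binding free energy function.

    Defaults are the classic free-energy-calibrated docking coefficients;
    a refit against kinase inhibition data would replace them as a table,
    not a code change.
    """

    vdw: float = 0.1485
    hbond: float = 0.0656
    elec: float = 0.1146
    tor: float = 0.3113
    sol: float = 0.1711

    def __post_init__(self) -> None:
        for name in ("vdw", "hbond", "elec", "tor", "sol"):
            if getattr(self, name) < 0:
                raise ValueError(f"weight {name} must be >= 0")


@dataclass(frozen=True)
class DielectricParams:
    """Sigmoidal distance-dependent dielectric eps(r).

    eps(r) = a + (eps_bulk - a) / (1 + k * exp(-lam * (eps_bulk - a) * r))

    rises monotonically from a protein-interior-like value near r = 0 to
    the bulk-water asymptote eps_bulk.  Defaults are the published
    constants of the sigmoidal screening function.
    """

    eps_bulk: float = 78.4
    lam: float = 0.003627
    k: float = 7.7839
    a: float = -8.5525

    def epsilon(self, r):
        """Evaluate eps(r); accepts scalars or arrays."""
        b = self.eps_bulk - self.a
        return self.a + b / (1.0 + self.k * np.exp(-self.lam * b * np.asarray(r)))


@dataclass(frozen=True)
class AngularParams:
    """Directionality weight E(t) of the hydrogen-bond term.

    E(t) = max(0, cos(t - ideal))**exponent with t the donor-H...acceptor
    angle in degrees.  E(ideal) = 1 and E vanishes 90 degrees off ideal.
    """

    ideal_deg: float = 180.0
    exponent: int = 2


@dataclass(frozen=True)
class HBondWell:
    """12-10 hydrogen-bond well between donor heavy atom and acceptor."""

    r0: float = 2.9    # heavy-heavy equilibrium distance, A
    eps: float = 5.0   # well depth, kcal/mol

    @property
    def c(self) -> float:
        return 5.0 * self.eps * self.r0 ** 12

    @property
    def d(self) -> float:
        return 6.0 * self.eps * self.r0 ** 10


class ParameterSet:
    """All constants of the binding free energy function.

    Parameters
    ----------
    atom_types
        Mapping type_code -> :class:`AtomTypeParams`.
    weights, angular, dielectric, hbond
        Term constants; see the respective dataclasses.
    sigma
        Width of the dehydration Gaussian, Angstrom.
    cutoff
        Nonbonded pair cutoff, Angstrom, applied to every pair sum.
    provenance
        Free-form notes on where each block of constants came from
        (defaults record that weights and solvation values are surrogate
        placeholders, not a refit).
    """

    def __init__(
        self,
        atom_types: dict[str, AtomTypeParams],
        weights: Weights | None = None,
        angular: AngularParams | None = None,
        dielectric: DielectricParams | None = None,
        hbond: HBondWell | None = None,
        sigma: float = 3.5,
        cutoff: float = 12.0,
        provenance: dict[str, str] | None = None,
    ) -> None:
        if sigma <= 0:
            raise ValueError("sigma must be > 0")
        for tp in atom_types.values():
            if tp.v < 0 or tp.occ_max <= 0:
                raise ValueError(f"invalid solvation row for type {tp.type_code}")
        self.atom_types = dict(atom_types)
        self.weights = weights or Weights()
        self.angular = angular or AngularParams()
        self.dielectric = dielectric or DielectricParams()
        self.hbond = hbond or HBondWell()
        self.sigma = float(sigma)
        self.cutoff = float(cutoff)
        self.provenance = provenance or {
            "weights": "classic free-energy-calibrated docking coefficients "
                       "(surrogate; not refit against kinase data)",
            "vdw": "AMBER-derived Rii/eps table",
            "dielectric": "published sigmoidal screening-function constants",
            "solvation": "documented placeholder solvent-contact table "
                         "(not a fitted set)",
        }
        self._type_index = {t: i for i, t in enumerate(sorted(self.atom_types))}
        self._build_matrices()

    # ------------------------------------------------------------------
    # construction helpers

    @classmethod
    def default(cls, **overrides) -> "ParameterSet":
        """The shipped parameter set (data/atom_types.txt + defaults)."""
        path = resources.files("hingedock.data").joinpath("atom_types.txt")
        with resources.as_file(path) as p:
            return cls.from_file(p, **overrides)

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "ParameterSet":
        """Parse a self-describing whitespace-delimited atom-type table."""
        atom_types: dict[str, AtomTypeParams] = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            cols = line.split()
            if len(cols) != 8:
                raise ValueError(
                    f"{path}:{lineno}: expected 8 columns, got {len(cols)}"
                )
            tp = AtomTypeParams(
                type_code=cols[0],
                element=cols[1],
                rii=float(cols[2]),
                eps=float(cols[3]),
                hb=cols[4],
                s=float(cols[5]),
                v=float(cols[6]),
                occ_max=float(cols[7]),
            )
            atom_types[tp.type_code] = tp
        if not atom_types:
            raise ValueError(f"no atom types found in {path}")
        return cls(atom_types, **overrides)

    def with_weights(self, **kw) -> "ParameterSet":
        """A copy with some term weights replaced (e.g. ``sol=0``)."""
        ps = ParameterSet(
            self.atom_types,
            weights=replace(self.weights, **kw),
            angular=self.angular,
            dielectric=self.dielectric,
            hbond=self.hbond,
            sigma=self.sigma,
            cutoff=self.cutoff,
            provenance=dict(self.provenance),
        )
        return ps

    # ------------------------------------------------------------------
    # lookups

    def __contains__(self, type_code: str) -> bool:
        return type_code in self.atom_types

    def type_params(self, type_code: str) -> AtomTypeParams:
        try:
            return self.atom_types[type_code]
        except KeyError:
            raise KeyError(
                f"atom type {type_code!r} not in parameter set "
                f"(known: {sorted(self.atom_types)})"
            ) from None

    def type_index(self, type_code: str) -> int:
        return self._type_index[self.type_params(type_code).type_code]

    def vdw_pair(self, ti: str, tj: str) -> tuple[float, float]:
        """(A_ij, B_ij) of the 12-6 potential for a type pair.

        Lorentz-Berthelot combination: R_ij = (Rii + Rjj)/2,
        eps_ij = sqrt(eps_i * eps_j); A = eps*R^12, B = 2*eps*R^6 so the
        minimum sits at R_ij with depth eps_ij.
        """
        a, b = self.type_params(ti), self.type_params(tj)
        rij = 0.5 * (a.rii + b.rii)
        eps = math.sqrt(a.eps * b.eps)
        return eps * rij ** 12, 2.0 * eps * rij ** 6

    def hbond_pair(self, ti: str, tj: str) -> tuple[float, float]:
        """(C_ij, D_ij) of the 12-10 potential for a donor/acceptor pair."""
        if not self.hbond_eligible(ti, tj):
            raise ValueError(f"type pair ({ti}, {tj}) is not hydrogen-bond eligible")
        return self.hbond.c, self.hbond.d

    def hbond_eligible(self, ti: str, tj: str) -> bool:
        """True iff one type is a donor heavy atom and the other an acceptor."""
        a, b = self.type_params(ti), self.type_params(tj)
        return (a.is_donor and b.is_acceptor) or (a.is_acceptor and b.is_donor)

    def solvation(self, type_code: str) -> tuple[float, float, float]:
        tp = self.type_params(type_code)
        return tp.s, tp.v, tp.occ_max

    def epsilon(self, r):
        return self.dielectric.epsilon(r)

    # ------------------------------------------------------------------
    # vectorized pair matrices (indexed by type_index)

    def _build_matrices(self) -> None:
        codes = sorted(self.atom_types)
        n = len(codes)
        A = np.zeros((n, n))
        B = np.zeros((n, n))
        elig = np.zeros((n, n), dtype=bool)
        for i, ti in enumerate(codes):
            for j, tj in enumerate(codes):
                A[i, j], B[i, j] = self.vdw_pair(ti, tj)
                elig[i, j] = self.hbond_eligible(ti, tj)
        self.A_matrix = A
        self.B_matrix = B
        self.hbond_eligible_matrix = elig
        self.s_array = np.array([self.atom_types[c].s for c in codes])
        self.v_array = np.array([self.atom_types[c].v for c in codes])
        self.occmax_array = np.array([self.atom_types[c].occ_max for c in codes])
        self.donor_array = np.array([self.atom_types[c].is_donor for c in codes])
        self.acceptor_array = np.array(
            [self.atom_types[c].is_acceptor for c in codes]
        )

    def type_indices(self, type_codes) -> np.ndarray:
        """Vector of matrix indices for a sequence of type codes."""
        return np.array([self.type_index(t) for t in type_codes], dtype=int)
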