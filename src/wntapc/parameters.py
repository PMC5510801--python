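"""Model constants, experiment contexts, and APC mutation descriptors.

The kinetic model tracks the canonical Wnt cascade in a cell carrying up to
two distinct APC species (one per allele).  All rate and equilibrium
constants live in :class:`KineticParameters`; assay geometry and ligand /
inhibitor totals live in :class:`ExperimentContext`.  Named APC mutations are
expressed as per-allele multipliers on three parameters only -- the fraction
of full-length APC expressed (``pt_fraction``), the APC--Axin dissociation
constant fold-change (``kd1_fold``) and the destruction-complex--beta-catenin
binding-rate fraction (``k6_fraction``) -- everything else is assumed
untouched by the mutation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

__all__ = [
    "AVOGADRO",
    "KineticParameters",
    "ExperimentContext",
    "AlleleSpec",
    "Genotype",
    "ParameterBundle",
    "ALLELE_CATALOG",
    "build_allele",
    "truncated_allele",
    "build_parameters",
    "wild_type_bundle",
    "partition_coefficients",
    "standard_context",
    "calibration_context",
]

AVOGADRO = 6.02214076e23  # 1/mol


def _require_positive(obj, names):
    for name in names:
        value = getattr(obj, name)
        if not (value > 0) or not math.isfinite(value):
            raise ValueError(f"{type(obj).__name__}.{name} must be strictly positive, got {value!r}")


def _require_nonnegative(obj, names):
    for name in names:
        value = getattr(obj, name)
        if value < 0 or not math.isfinite(value):
            raise ValueError(f"{type(obj).__name__}.{name} must be nonnegative, got {value!r}")


@dataclass(frozen=True)
class KineticParameters:
    """Cell-intrinsic rate constants and protein totals (wild-type values).

    Units: second-order rates in 1/(M*s); first-order rates in 1/s; ``k7``
    in M/s; dissociation constants and protein totals in M; ``Vcell`` in
    litres.  ``k_m6`` lumps beta-catenin phosphorylation, dissociation from
    the destruction complex, and degradation into a single step, which is
    why the complex-bound beta-catenin leaving through it never returns to
    the free pool.
    """

    k1: float = 4.33e4       # sFRP1-Wnt binding
    k_m1: float = 4.86e-4    # sFRP1-Wnt dissociation
    k2: float = 7.9e4        # Wnt-Frizzled binding
    k_m2: float = 4.7e-4     # Wnt-Frizzled dissociation
    k3: float = 1.3e7        # Frizzled/Wnt-LRP binding
    k_m3: float = 0.1        # ternary complex dissociation
    k4: float = 1.03e6       # Dkk1-LRP binding
    k_m4: float = 5.05e-4    # Dkk1-LRP dissociation
    k5: float = 4.84e5       # ternary complex-destruction complex binding
    k_m5: float = 1e-4       # ternary complex-destruction complex dissociation
    k6_base: float = 2.72e5  # destruction complex-beta-catenin binding (WT)
    k_m6: float = 1.25       # lumped phosphorylation + dissociation + degradation
    k7: float = 1.39e-9      # beta-catenin production, M/s
    k8: float = 4.2e-6       # complex-independent beta-catenin degradation
    KD1_base: float = 5e-8   # APC : Axin/APC dissociation constant (WT), M
    KD2: float = 1e-8        # GSK : destruction-complex dissociation constant, M
    PT_base: float = 3.4e-8  # total APC, M
    AT: float = 3e-8         # total Axin, M
    GT: float = 2.1e-8       # total GSK3beta, M
    Vcell: float = 3.5e-13   # cell volume, l

    def __post_init__(self):
        _require_positive(self, [f.name for f in fields(self)])


@dataclass(frozen=True)
class ExperimentContext:
    """Assay-level quantities: ligand/inhibitor totals and well geometry.

    ``FT``/``LT`` are receptor copy numbers per cell; soluble totals are
    molar concentrations in the well.  The partition coefficients derived
    from the geometry translate membrane copy numbers into intracellular
    (``Ksu_in``) or extracellular (``Ksu_ex``) concentrations and are always
    recomputed from ``Vexp``/``Ncell``/``Vcell``, never stored.
    """

    WT_total: float = 5e-9   # total Wnt, M
    ST_total: float = 0.0    # total sFRP1, M
    DT_total: float = 0.0    # total Dkk1, M
    FT: float = 1.01e4       # Frizzled receptors per cell
    LT: float = 4e3          # LRP receptors per cell
    Vexp: float = 3e-3       # well volume, l
    Ncell: float = 1e6       # cells per well

    def __post_init__(self):
        _require_nonnegative(self, ["WT_total", "ST_total", "DT_total"])
        _require_positive(self, ["FT", "LT", "Vexp", "Ncell"])

    def with_dose(self, inhibitor: str, dose: float) -> "ExperimentContext":
        """Return a copy with the given inhibitor total set to ``dose`` (M)."""
        key = {"sFRP1": "ST_total", "Dkk1": "DT_total"}.get(inhibitor)
        if key is None:
            raise ValueError(f"unknown inhibitor {inhibitor!r}; expected 'sFRP1' or 'Dkk1'")
        return replace(self, **{key: dose})

    def untreated(self) -> "ExperimentContext":
        return replace(self, ST_total=0.0, DT_total=0.0)


def standard_context(**overrides) -> ExperimentContext:
    """The tissue-culture context used for all mutant simulations.

    5 nM Wnt in a 3 ml well of 1e6 cells; inhibitor-free unless overridden.
    """
    return replace(ExperimentContext(), **overrides) if overrides else ExperimentContext()


def calibration_context(**overrides) -> ExperimentContext:
    """The small-well, low-cell-count context of the beta-catenin vs Wnt
    dose-response calibration assay (20 ul, 5e3 cells, Wnt titrated)."""
    ctx = ExperimentContext(WT_total=0.0, Vexp=2e-5, Ncell=5e3)
    return replace(ctx, **overrides) if overrides else ctx


def partition_coefficients(ctx: ExperimentContext, base: KineticParameters) -> tuple[float, float]:
    """Return ``(Ksu_ex, Ksu_in)`` in molar per (molecule/cell).

    ``Ksu_in = 1/(N_A * Vcell)`` converts a per-cell copy number to the
    intracellular concentration it represents; ``Ksu_ex = Ncell/(N_A * Vexp)``
    converts it to the concentration the same molecules would contribute to
    the shared extracellular medium.
    """
    if not (ctx.Vexp > 0 and ctx.Ncell > 0 and base.Vcell > 0):
        raise ValueError("Vexp, Ncell and Vcell must all be positive")
    ksu_in = 1.0 / (AVOGADRO * base.Vcell)
    ksu_ex = ctx.Ncell / (AVOGADRO * ctx.Vexp)
    return ksu_ex, ksu_in


@dataclass(frozen=True)
class AlleleSpec:
    """Effect of one APC allele on the three mutation-sensitive parameters.

    ``pt_fraction`` scales the full-length APC expressed from this allele
    relative to one wild-type allele (which contributes half the wild-type
    total), ``kd1_fold`` multiplies the APC--Axin dissociation constant (>= 1: a
    truncated protein binds Axin no better than wild type), and
    ``k6_fraction`` scales the destruction-complex--beta-catenin binding
    rate (<= 1: a complex built on truncated APC degrades beta-catenin no
    faster than wild type).
    """

    name: str
    pt_fraction: float
    kd1_fold: float = 1.0
    k6_fraction: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.pt_fraction <= 1.0:
            raise ValueError(f"pt_fraction must lie in [0, 1], got {self.pt_fraction}")
        if self.kd1_fold < 1.0:
            raise ValueError(f"kd1_fold must be >= 1, got {self.kd1_fold}")
        if not 0.0 < self.k6_fraction <= 1.0:
            raise ValueError(f"k6_fraction must lie in (0, 1], got {self.k6_fraction}")

    @property
    def kinetics(self) -> tuple[float, float]:
        return (self.kd1_fold, self.k6_fraction)


#: Named alleles whose effect reduces to expression of full-length APC.
#: The truncating alleles (1572T, min) are not listed because their
#: (kd1_fold, k6_fraction) pair is under-determined and must come from
#: calibration -- see :mod:`wntapc.calibration` and :func:`truncated_allele`.
ALLELE_CATALOG: dict[str, AlleleSpec] = {
    "WT": AlleleSpec("WT", 1.0, 1.0, 1.0),
    "1638T": AlleleSpec("1638T", 1.0, 1.0, 1.0),   # silent: indistinguishable from WT
    "1638N": AlleleSpec("1638N", 0.02, 1.0, 1.0),  # near-null allele
    "neoR": AlleleSpec("neoR", 0.2, 1.0, 1.0),
    "neoF": AlleleSpec("neoF", 0.1, 1.0, 1.0),
}

_TRUNCATING = ("1572T", "min")


def build_allele(name: str) -> AlleleSpec:
    """Look up a catalog allele by label.

    Raises a :class:`ValueError` naming the label if it is unknown, with a
    pointer to :func:`truncated_allele` for the truncating alleles whose
    kinetic parameters are calibration outputs rather than catalog constants.
    """
    try:
        return ALLELE_CATALOG[name]
    except KeyError:
        if name in _TRUNCATING:
            raise ValueError(
                f"allele {name!r} is a truncating mutation whose (kd1_fold, k6_fraction) "
                "lie on a calibrated locus; construct it explicitly with "
                "truncated_allele(name, kd1_fold, k6_fraction)"
            ) from None
        raise ValueError(
            f"unknown allele label {name!r}; known labels: {sorted(ALLELE_CATALOG)}"
        ) from None


def truncated_allele(name: str, kd1_fold: float, k6_fraction: float) -> AlleleSpec:
    """An allele expressing full-length amounts of a truncated APC protein."""
    return AlleleSpec(name, 1.0, kd1_fold, k6_fraction)


@dataclass(frozen=True)
class Genotype:
    """Unordered pair of APC alleles; parameter building is symmetric."""

    allele1: AlleleSpec
    allele2: AlleleSpec

    @classmethod
    def from_string(cls, spec: str) -> "Genotype":
        """Parse ``"name1/name2"`` using the catalog, e.g. ``"1638N/1638T"``."""
        parts = spec.split("/")
        if len(parts) != 2:
            raise ValueError(f"genotype must be 'allele1/allele2', got {spec!r}")
        return cls(build_allele(parts[0].strip()), build_allele(parts[1].strip()))

    @classmethod
    def homozygous(cls, allele: AlleleSpec) -> "Genotype":
        return cls(allele, allele)

    @property
    def label(self) -> str:
        return f"{self.allele1.name}/{self.allele2.name}"


@dataclass(frozen=True)
class ParameterBundle:
    """Concrete two-species parameter set for a genotype.

    The unprimed species (``PT``, ``KD1``, ``k6``) corresponds to one APC
    type, the primed (``PTp``, ``KD1p``, ``k6p``) to the other.  When the
    two alleles share kinetics the bundle collapses to the homozygous form:
    their expression is summed into the unprimed pool and ``PTp == 0``.
    """

    base: KineticParameters
    label: str
    PT: float
    KD1: float
    k6: float
    PTp: float = 0.0
    KD1p: float = field(default=0.0)
    k6p: float = field(default=0.0)

    @property
    def homozygous(self) -> bool:
        return self.PTp == 0.0


def build_parameters(genotype: Genotype, base: KineticParameters | None = None) -> ParameterBundle:
    """Translate a genotype into a concrete two-species parameter bundle.

    Each allele contributes half the wild-type APC total scaled by its
    expression fraction; its kinetic multipliers act on the wild-type
    ``KD1_base`` / ``k6_base``.  Alleles with identical kinetics (whatever
    their expression levels) produce a single APC species and are merged.
    """
    base = base if base is not None else KineticParameters()
    a1, a2 = genotype.allele1, genotype.allele2
    half = base.PT_base / 2.0
    pt1, pt2 = a1.pt_fraction * half, a2.pt_fraction * half
    if a1.kinetics == a2.kinetics:
        return ParameterBundle(
            base=base,
            label=f"{a1.name}/{a2.name}",
            PT=pt1 + pt2,
            KD1=a1.kd1_fold * base.KD1_base,
            k6=a1.k6_fraction * base.k6_base,
            PTp=0.0,
            KD1p=base.KD1_base,
            k6p=base.k6_base,
        )
    return ParameterBundle(
        base=base,
        label=f"{a1.name}/{a2.name}",
        PT=pt1,
        KD1=a1.kd1_fold * base.KD1_base,
        k6=a1.k6_fraction * base.k6_base,
        PTp=pt2,
        KD1p=a2.kd1_fold * base.KD1_base,
        k6p=a2.k6_fraction * base.k6_base,
    )


def wild_type_bundle(base: KineticParameters | None = None) -> ParameterBundle:
    return build_parameters(Genotype.from_string("WT/WT"), base)
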