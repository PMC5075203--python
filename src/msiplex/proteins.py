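"""Mutation logic, per-cell expression and channel rendering for six proteins.

The six markers are the four DNA mismatch-repair (MMR) proteins MLH1, PMS2,
MSH2 and MSH6 plus the tumour suppressors P53 and PTEN.  The MMR proteins work
as heterodimers (MLH1-PMS2 and MSH2-MSH6), so loss of MLH1 also abolishes PMS2
staining and loss of MSH2 abolishes MSH6; loss of PMS2 or MSH6 is isolated.
Stromal cells always retain MMR staining — the pathologist's positive control
— while a mutation silences the protein in the epithelium only.

Population-representative sampling uses the published clinical rates: an MMR
mutation occurs with 15 % probability; given a mutation the affected gene is
MLH1 / MSH2 / MSH6 / PMS2 with probability 50 / 40 / 7 / 3 %.  P53 is flagged
over-expressed (more than half of epithelial cells staining) with probability
50 % in microsatellite-stable samples and 20 % in MMR-mutated ones.  PTEN is
expressed in a uniformly drawn 30-70 % share of stromal cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .organelles import OrganelleInstance
from .raster import CompartmentRasters, rasterize_sample
from .scaffold import TissueSample

PROTEINS = ("MLH1", "PMS2", "MSH2", "MSH6", "P53", "PTEN")
MMR_GENES = ("MLH1", "PMS2", "MSH2", "MSH6")

MMR_MUTATION_PROBABILITY = 0.15
GENE_SPLIT = {"MLH1": 0.50, "MSH2": 0.40, "MSH6": 0.07, "PMS2": 0.03}
P53_OVEREXPRESSION_PROBABILITY = {"non_msi": 0.50, "msi": 0.20}
PTEN_STROMAL_RANGE = (0.30, 0.70)

STRONG = "strong"
WEAK = "weak"
DEFAULT_LEVELS = {STRONG: 1.0, WEAK: 0.3}

# Subcellular compartment profiles.  MSH2 keeps weak nucleolar staining in
# addition to its strong nuclear signal (the curated location tables and the
# imaging behaviour differ slightly; the imaging behaviour is modelled).
_PROFILES: dict[str, dict[str, str]] = {
    "MLH1": {"nucleoli": STRONG, "nucleus": WEAK, "cytoplasm": WEAK},
    "PMS2": {"nucleus_minus_nucleoli": STRONG, "cytoplasm": WEAK},
    "MSH2": {"nucleus_minus_nucleoli": STRONG, "nucleoli": WEAK,
             "vesicles": STRONG},
    "MSH6": {"nucleus_minus_nucleoli": STRONG, "golgi": STRONG,
             "vesicles": STRONG, "cytoplasm": WEAK},
    "P53": {"nucleus_minus_nucleoli": STRONG},
    "PTEN": {"nucleus_minus_nucleoli": STRONG, "cytoplasm": STRONG},
}

DEFAULT_EPITHELIAL_FRACTIONS = {
    "MLH1": 0.9, "PMS2": 0.85, "MSH2": 0.9, "MSH6": 0.85, "PTEN": 0.8,
}


class ConfigurationError(ValueError):
    pass


class MissingCompartmentError(KeyError):
    pass


@dataclass
class MutationStatus:
    mutated_gene: str  # "none" or one of MMR_GENES
    p53_overexpressed: bool
    epithelial_fraction: dict[str, float]
    pten_stromal_fraction: float


def lost_proteins(mutated_gene: str) -> set[str]:
    """Proteins with abolished epithelial staining for a given mutated gene."""
    table = {
        "none": set(),
        "MLH1": {"MLH1", "PMS2"},
        "PMS2": {"PMS2"},
        "MSH2": {"MSH2", "MSH6"},
        "MSH6": {"MSH6"},
    }
    try:
        return set(table[mutated_gene])
    except KeyError:
        raise ConfigurationError(f"unknown MMR gene {mutated_gene!r}")


def sample_mutation_status(population_representative: bool = True,
                           user_overrides: Mapping | None = None,
                           rng: np.random.Generator | None = None
                           ) -> MutationStatus:
    """Draw a sample-level mutation status.

    With ``population_representative`` the clinical rates above are used; the
    draw order (mutation, gene, P53, PTEN, fractions) is fixed so a seeded
    generator reproduces the status exactly.  Overrides may pin
    ``mutated_gene``, ``p53_overexpressed`` or ``epithelial_fraction`` entries.
    """
    rng = rng if rng is not None else np.random.default_rng()
    overrides = dict(user_overrides or {})

    gene = overrides.get("mutated_gene")
    if gene is not None:
        if gene != "none" and gene not in MMR_GENES:
            raise ConfigurationError(f"unknown MMR gene {gene!r}")
    elif population_representative:
        if rng.uniform() < MMR_MUTATION_PROBABILITY:
            genes = list(GENE_SPLIT)
            probs = np.array([GENE_SPLIT[g] for g in genes])
            gene = genes[int(rng.choice(len(genes), p=probs))]
        else:
            gene = "none"
    else:
        raise ConfigurationError(
            "non-representative sampling requires an explicit mutated_gene")

    if "p53_overexpressed" in overrides:
        p53_over = bool(overrides["p53_overexpressed"])
        rng.uniform()  # keep the stream aligned with the representative path
    else:
        p_over = (P53_OVEREXPRESSION_PROBABILITY["non_msi"] if gene == "none"
                  else P53_OVEREXPRESSION_PROBABILITY["msi"])
        p53_over = bool(rng.uniform() < p_over)

    pten_stromal = float(rng.uniform(*PTEN_STROMAL_RANGE))

    fractions = dict(DEFAULT_EPITHELIAL_FRACTIONS)
    # over-expression means more than half of epithelial cells staining
    if p53_over:
        fractions["P53"] = float(rng.uniform(0.5, 1.0))
    else:
        fractions["P53"] = float(rng.uniform(0.05, 0.5))
    fractions.update(overrides.get("epithelial_fraction", {}))

    return MutationStatus(mutated_gene=gene, p53_overexpressed=p53_over,
                          epithelial_fraction=fractions,
                          pten_stromal_fraction=pten_stromal)


@dataclass
class ExpressionMap:
    """Which cells express each protein, plus the compartment profiles."""

    expressors: dict[str, set[int]]
    profiles: dict[str, dict[str, str]] = field(
        default_factory=lambda: {p: compartment_profile(p) for p in PROTEINS})

    def expresses(self, cell_id: int, protein: str) -> bool:
        return cell_id in self.expressors[protein]


def compartment_profile(protein: str) -> dict[str, str]:
    try:
        return dict(_PROFILES[protein])
    except KeyError:
        raise ConfigurationError(f"unknown protein {protein!r}")


def _subset(ids: Sequence[int], k: int, rng: np.random.Generator) -> set[int]:
    ids = sorted(ids)
    k = min(max(k, 0), len(ids))
    if k == 0:
        return set()
    return set(int(i) for i in rng.choice(ids, size=k, replace=False))


def assign_expression(sample: TissueSample, status: MutationStatus,
                      rng: np.random.Generator) -> ExpressionMap:
    """Per-cell expression respecting epistasis, subsets and stromal controls.

    Goblet cells follow the epithelial rules.  PMS2 epithelial expressors are
    a subset of MLH1 expressors and MSH6 of MSH2 (binding-partner logic); all
    stromal cells express every MMR protein; P53 is never stromal.
    """
    epi = sorted(c.cell_id for c in sample.cells
                 if c.phenotype in ("epithelial", "goblet"))
    stromal = sorted(c.cell_id for c in sample.cells
                     if c.phenotype == "stromal")
    lost = lost_proteins(status.mutated_gene)
    n_epi = len(epi)
    frac = status.epithelial_fraction

    def epi_set(protein: str, pool: Sequence[int]) -> set[int]:
        if protein in lost:
            return set()
        k = int(round(frac.get(protein, 0.0) * n_epi))
        return _subset(pool, k, rng)

    expr: dict[str, set[int]] = {}
    expr["MLH1"] = set(stromal) | epi_set("MLH1", epi)
    expr["PMS2"] = set(stromal) | epi_set("PMS2", sorted(expr["MLH1"] - set(stromal)))
    expr["MSH2"] = set(stromal) | epi_set("MSH2", epi)
    expr["MSH6"] = set(stromal) | epi_set("MSH6", sorted(expr["MSH2"] - set(stromal)))
    expr["P53"] = epi_set("P53", epi)  # never stromal
    n_strom_expr = int(round(status.pten_stromal_fraction * len(stromal)))
    expr["PTEN"] = _subset(stromal, n_strom_expr, rng) | epi_set("PTEN", epi)
    return ExpressionMap(expressors=expr)


def procedural_texture(shape: tuple[int, int], kind: str = "smooth_noise",
                       params: Mapping | None = None,
                       rng: np.random.Generator | None = None) -> np.ndarray:
    """Octave-summed band-limited value noise in [0, 1] with mean near 0.5.

    ``chromatin`` adds a clumpy high-contrast nonlinearity, emulating the
    granular heterochromatin pattern of a stained nucleus.  With amplitude 0
    the field is constant.  Deterministic for a seeded generator.
    """
    if shape[0] <= 0 or shape[1] <= 0:
        raise ValueError("texture shape must be positive")
    p = dict(params or {})
    octaves = int(p.get("octaves", 4))
    persistence = float(p.get("persistence", 0.55))
    base_period = float(p.get("base_period", 64.0))
    amplitude = float(p.get("amplitude", 0.35))
    rng = rng if rng is not None else np.random.default_rng()

    acc = np.zeros(shape, dtype=float)
    amp, period, total = 1.0, base_period, 0.0
    for _ in range(octaves):
        ny = max(int(np.ceil(shape[0] / period)) + 2, 2)
        nx = max(int(np.ceil(shape[1] / period)) + 2, 2)
        grid = rng.random((ny, nx))
        field_big = ndimage.zoom(grid, period, order=3)
        acc += amp * (field_big[:shape[0], :shape[1]] - 0.5)
        total += amp
        amp *= persistence
        period = max(period / 2.0, 2.0)
    acc /= total
    if kind == "chromatin":
        acc = np.tanh(2.5 * acc) / 1.2  # clumpy, higher contrast
    elif kind != "smooth_noise":
        raise ValueError(f"unknown texture kind {kind!r}")
    out = 0.5 + 2.0 * amplitude * acc
    return np.clip(out, 0.0, 1.0)


def render_channel(protein: str, sample: TissueSample,
                   organelles: Mapping[str, Sequence[OrganelleInstance]],
                   expression: ExpressionMap,
                   rng: np.random.Generator,
                   rasters: CompartmentRasters | None = None,
                   levels: Mapping[str, float] | None = None) -> np.ndarray:
    """Render one protein channel: compartment intensities times texture.

    Weak compartments are painted first so strong ones override where they
    overlap (e.g. nucleoli on top of the whole-nucleus background of MLH1).
    """
    profile = compartment_profile(protein)
    if rasters is None:
        rasters = rasterize_sample(sample, organelles)
    lv = dict(DEFAULT_LEVELS)
    lv.update(levels or {})
    expressing = np.array(sorted(expression.expressors[protein]), dtype=np.int32)
    out = np.zeros(rasters.shape, dtype=float)
    kind = "chromatin" if protein == "MSH2" else "smooth_noise"
    texture = procedural_texture(rasters.shape, kind=kind, rng=rng)
    ordered = sorted(profile.items(), key=lambda kv: lv[kv[1]])
    for compartment, level in ordered:
        try:
            labels = rasters.compartment_mask(compartment)
        except KeyError as exc:
            raise MissingCompartmentError(str(exc))
        if expressing.size == 0:
            continue
        mask = np.isin(labels, expressing)
        out[mask] = lv[level] * texture[mask]
    return np.clip(out, 0.0, 1.0)
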