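"""Planted-signal simulator for the two-timepoint denervation drug study.

The generator emulates the statistical structure the analysis assumes: a
2x2 design (7 vs 35 days of denervation x vehicle vs nandrolone, 3 arrays
per group), log-normal baseline expression, per-array scale factors (so that
median normalization is load-bearing, not decorative), Gaussian log2 residual
noise, and planted effects:

* ``n_drug7`` genes respond to the drug at 7 days,
* ``n_drug35`` genes respond at 35 days *and are not time-confounded*
  (these constitute the truth for Pool B),
* ``n_shared`` genes respond at both timepoints (truth for Pool C; same
  direction at both timepoints by default, opposite if requested),
* ``n_time`` genes change with time alone (all 35-day arrays shift; truth
  for Pool E), of which ``round(fraction_concordant * n_time)`` additionally
  receive a 35-day drug effect in the *same* direction as their time trend —
  the time-confounded genes the concordant subtraction exists to remove
  (together with the ``n_drug35`` genes they are the truth for Pool D).

Defaults mirror the study conditions: 124 / 122 / 20 planted drug genes,
318 time genes with 154 concordant (so the planted Pool D holds 276 genes),
an 8-fold effect and 0.15 log2 residual sd.

Also provided: triplicate Ct tables with a per-sample loading shift shared
by target and reference gene, and muscle-weight vectors with a target
correlation to a chosen gene's expression (emulating the negative RCAN2 and
positive ApoD weight relationships in atrophying muscle).

Every generator is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .expression_io import (
    NANDROLONE,
    VEHICLE,
    ExpressionMatrix,
    ProbeAnnotation,
    SampleDesign,
)

GROUP_ORDER = ((7, VEHICLE), (7, NANDROLONE), (35, VEHICLE), (35, NANDROLONE))


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the expression-matrix generator."""

    n_probes: int = 10_000
    arrays_per_group: int = 3
    baseline_mean: float = 8.0        # log2 intensity
    baseline_sd: float = 1.5          # log2
    scale_sd: float = 0.2             # per-array scale factor, log2
    noise_sd: float = 0.15            # residual, log2
    n_drug7: int = 124
    n_drug35: int = 122               # drug-responsive at 35 d, not confounded
    n_shared: int = 20
    n_time: int = 318
    fraction_concordant: float = 154 / 318
    effect_log2: float = 3.0          # 8-fold planted drug effect
    time_effect_log2: float = 3.0
    probes_per_gene: tuple[tuple[int, float], ...] = ((1, 1.0),)
    fraction_unannotated: float = 0.3
    shared_opposite: bool = False     # flip the 35-d direction of shared genes

    def __post_init__(self) -> None:
        if self.n_shared > min(self.n_drug7, self.n_drug35):
            raise ValidationError("n_shared cannot exceed n_drug7 or n_drug35")
        if not 0 <= self.fraction_concordant <= 1:
            raise ValidationError("fraction_concordant must be in [0, 1]")
        for name in ("baseline_sd", "scale_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.arrays_per_group < 2:
            raise ValidationError("arrays_per_group must be >= 2")
        counts = np.array([c for c, _ in self.probes_per_gene])
        probs = np.array([p for _, p in self.probes_per_gene])
        if (counts < 1).any() or not np.isclose(probs.sum(), 1.0):
            raise ValidationError("probes_per_gene must be a distribution "
                                  "over positive counts")

    @property
    def n_concordant(self) -> int:
        return int(round(self.fraction_concordant * self.n_time))

    @property
    def n_planted_genes(self) -> int:
        return (self.n_drug7 - self.n_shared) + self.n_shared \
            + (self.n_drug35 - self.n_shared) + self.n_time


@dataclass(frozen=True)
class SyntheticTruth:
    """Ledger of what was planted, for scoring recovered pools."""

    genes: pd.DataFrame       # index: gene_symbol; bool membership columns
    #   in_drug7, in_drug35 (Pool-D truth), in_time, concordant
    #   + dir7, dir35, dir_time (+1/-1/0)
    scale_factors: pd.Series  # index: array_id; log2 scale factor

    def pool_genes(self, which: str) -> set[str]:
        g = self.genes
        return {
            "A": set(g.index[g["in_drug7"]]),
            "D": set(g.index[g["in_drug35"]]),
            "E": set(g.index[g["in_time"]]),
            "B": set(g.index[g["in_drug35"] & ~g["concordant"]]),
            "C": set(g.index[g["in_drug7"] & g["in_drug35"] & ~g["concordant"]]),
        }[which]


def _choose_directions(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.choice([-1.0, 1.0], size=n)


def generate_expression(
    config: SyntheticConfig = SyntheticConfig(), seed: int = 0
) -> tuple[ExpressionMatrix, SampleDesign, ProbeAnnotation, SyntheticTruth]:
    """Simulate one complete microarray study.

    Intensity model (before the pipeline's own normalization):
    ``value[p, a] = 2^(baseline_p + effects[p, a] + scale_a + noise[p, a])``.
    """
    rng = np.random.default_rng(seed)
    n_arrays = 4 * config.arrays_per_group

    # --- design -----------------------------------------------------------
    rows = []
    for tp, tr in GROUP_ORDER:
        for rep in range(1, config.arrays_per_group + 1):
            short = "nan" if tr == NANDROLONE else "veh"
            rows.append((f"{short}{tp}_r{rep}", tp, tr, rep))
    design = SampleDesign(
        pd.DataFrame(rows, columns=["array_id", "timepoint", "treatment",
                                    "replicate"])
    )
    array_ids = design.array_ids
    col_groups = {
        g: [i for i, a in enumerate(array_ids)
            if (design.table.iloc[i]["timepoint"],
                design.table.iloc[i]["treatment"]) == g]
        for g in GROUP_ORDER
    }

    # --- probe -> gene map ------------------------------------------------
    n_annotated = int(round((1 - config.fraction_unannotated) * config.n_probes))
    counts = np.array([c for c, _ in config.probes_per_gene])
    probs = np.array([p for _, p in config.probes_per_gene])
    per_gene: list[int] = []
    total = 0
    while total < n_annotated:
        c = int(rng.choice(counts, p=probs))
        c = min(c, n_annotated - total)
        per_gene.append(c)
        total += c
    n_genes = len(per_gene)
    if config.n_planted_genes > n_genes:
        raise ValidationError(
            f"planted sets need {config.n_planted_genes} genes but only "
            f"{n_genes} annotated genes exist; increase n_probes or lower "
            "fraction_unannotated"
        )
    gene_symbols = [f"G{i:05d}" for i in range(n_genes)]
    probe_gene: list[str] = []
    for sym, c in zip(gene_symbols, per_gene):
        probe_gene.extend([sym] * c)
    probe_gene.extend([""] * (config.n_probes - n_annotated))
    probe_ids = [f"probe_{i:05d}" for i in range(config.n_probes)]
    # shuffle so planted probes are not clustered at the top of the matrix
    perm = rng.permutation(config.n_probes)
    probe_gene = [probe_gene[i] for i in perm]
    annotation = ProbeAnnotation.from_mapping(dict(zip(probe_ids, probe_gene)))

    # --- planted gene sets ------------------------------------------------
    chosen = rng.choice(n_genes, size=config.n_planted_genes, replace=False)
    sizes = [config.n_shared, config.n_drug7 - config.n_shared,
             config.n_drug35 - config.n_shared, config.n_time]
    edges = np.cumsum([0] + sizes)
    shared = [gene_symbols[i] for i in chosen[edges[0]:edges[1]]]
    drug7_only = [gene_symbols[i] for i in chosen[edges[1]:edges[2]]]
    drug35_only = [gene_symbols[i] for i in chosen[edges[2]:edges[3]]]
    time_genes = [gene_symbols[i] for i in chosen[edges[3]:edges[4]]]
    concordant = time_genes[: config.n_concordant]

    truth = pd.DataFrame(
        0.0, index=pd.Index(sorted(gene_symbols), name="gene_symbol"),
        columns=["dir7", "dir35", "dir_time"],
    )
    dir_shared7 = _choose_directions(rng, len(shared))
    dir_shared35 = -dir_shared7 if config.shared_opposite else dir_shared7
    truth.loc[shared, "dir7"] = dir_shared7
    truth.loc[shared, "dir35"] = dir_shared35
    truth.loc[drug7_only, "dir7"] = _choose_directions(rng, len(drug7_only))
    truth.loc[drug35_only, "dir35"] = _choose_directions(rng, len(drug35_only))
    dir_time = _choose_directions(rng, len(time_genes))
    truth.loc[time_genes, "dir_time"] = dir_time
    # concordant genes get a 35-day drug effect in their time direction
    truth.loc[concordant, "dir35"] = truth.loc[concordant, "dir_time"]

    truth["in_drug7"] = truth["dir7"] != 0
    truth["in_drug35"] = truth["dir35"] != 0
    truth["in_time"] = truth["dir_time"] != 0
    truth["concordant"] = truth.index.isin(concordant)

    # --- assemble log2 values --------------------------------------------
    baseline = rng.normal(config.baseline_mean, config.baseline_sd,
                          size=config.n_probes)
    scale = rng.normal(0.0, config.scale_sd, size=n_arrays)
    noise = rng.normal(0.0, config.noise_sd, size=(config.n_probes, n_arrays))

    log2v = baseline[:, None] + scale[None, :] + noise
    gene_of_probe = pd.Series(probe_gene, index=probe_ids)
    probe_dir = truth[["dir7", "dir35", "dir_time"]].reindex(
        gene_of_probe.to_numpy()
    ).fillna(0.0).to_numpy()
    nan7_cols = col_groups[(7, NANDROLONE)]
    nan35_cols = col_groups[(35, NANDROLONE)]
    day35_cols = col_groups[(35, VEHICLE)] + col_groups[(35, NANDROLONE)]
    for c in nan7_cols:
        log2v[:, c] += probe_dir[:, 0] * config.effect_log2
    for c in nan35_cols:
        log2v[:, c] += probe_dir[:, 1] * config.effect_log2
    for c in day35_cols:
        log2v[:, c] += probe_dir[:, 2] * config.time_effect_log2

    matrix = ExpressionMatrix(
        pd.DataFrame(np.exp2(log2v), index=pd.Index(probe_ids, name="probe_id"),
                     columns=array_ids)
    )
    truth_obj = SyntheticTruth(
        genes=truth[["in_drug7", "in_drug35", "in_time", "concordant",
                     "dir7", "dir35", "dir_time"]],
        scale_factors=pd.Series(scale, index=array_ids, name="log2_scale"),
    )
    return matrix, design, annotation, truth_obj


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------

def generate_ct_table(
    true_folds: dict[str, float],
    n_per_group: int = 8,
    ct_noise_sd: float = 0.2,
    seed: int = 0,
    gene: str = "GENE",
    reference_gene: str = "18S",
    reference_group: str | None = None,
    n_replicates: int = 3,
    base_ct: float = 25.0,
    reference_ct: float = 12.0,
    loading_sd: float = 0.5,
):
    """Simulate a triplicate Ct table for one target gene across groups.

    ``true_folds`` maps group label -> expression fold relative to the
    reference group (whose fold should be 1).  Each sample carries a random
    loading shift added to both target and reference-gene wells, so the
    ΔΔCt math must cancel it.  Target wells follow
    ``Ct = base_ct - log2(fold) + shift + noise``.
    """
    from .quantify import CtTable

    folds = dict(true_folds)
    for g, f in folds.items():
        if not f > 0:
            raise ValidationError(f"group {g!r}: fold must be positive, got {f}")
    if reference_group is None:
        reference_group = next(iter(folds))
    rng = np.random.default_rng(seed)
    rows = []
    groups: dict[str, str] = {}
    for g, fold in folds.items():
        for i in range(n_per_group):
            sample = f"{g}_s{i + 1}"
            groups[sample] = g
            shift = rng.normal(0.0, loading_sd)
            for _ in range(n_replicates):
                rows.append((sample, gene,
                             base_ct - np.log2(fold) + shift
                             + rng.normal(0.0, ct_noise_sd)))
            for _ in range(n_replicates):
                rows.append((sample, reference_gene,
                             reference_ct + shift
                             + rng.normal(0.0, ct_noise_sd)))
    data = pd.DataFrame(rows, columns=["sample", "gene", "ct"])
    return CtTable(data=data, groups=groups, reference_gene=reference_gene,
                   reference_group=reference_group)


# ---------------------------------------------------------------------------
# band intensities and muscle weights
# ---------------------------------------------------------------------------

def generate_band_intensities(
    true_ratios: dict[str, float],
    n_per_group: int = 8,
    cv: float = 0.10,
    seed: int = 0,
    reference_level: float = 1000.0,
) -> pd.DataFrame:
    """Simulate western-blot band intensities with log-normal noise.

    Returns a DataFrame with columns ``sample``, ``group``, ``target``,
    ``reference`` whose target/reference ratio is centred on the group's
    true ratio.
    """
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(cv**2))
    rows = []
    for g, ratio in true_ratios.items():
        if not ratio > 0:
            raise ValidationError(f"group {g!r}: ratio must be positive")
        for i in range(n_per_group):
            ref = reference_level * rng.lognormal(0.0, sigma)
            tgt = ratio * ref * rng.lognormal(0.0, sigma)
            rows.append((f"{g}_s{i + 1}", g, tgt, ref))
    return pd.DataFrame(rows, columns=["sample", "group", "target", "reference"])


def generate_weights(
    expression: np.ndarray,
    target_r: float,
    seed: int = 0,
    mean_weight: float = 0.9,
    sd_weight: float = 0.12,
) -> np.ndarray:
    """Muscle weights correlated with a gene's expression at level ``target_r``.

    Weights are ``r * z(x) + sqrt(1 - r^2) * noise`` rescaled to gram units
    (default: denervated rat gastrocnemius around 0.9 g), so the expected
    sample correlation with ``expression`` is ``target_r``.
    """
    x = np.asarray(expression, dtype=float)
    if x.ndim != 1 or len(x) < 3:
        raise ValidationError("expression vector needs at least 3 samples")
    if x.std() == 0:
        raise ValidationError("expression vector is constant (degenerate)")
    if not abs(target_r) < 1:
        raise ValidationError("|target_r| must be < 1")
    rng = np.random.default_rng(seed)
    z = (x - x.mean()) / x.std()
    eps = rng.standard_normal(len(x))
    eps = (eps - eps.mean()) / eps.std()
    w = target_r * z + np.sqrt(1 - target_r**2) * eps
    return mean_weight + sd_weight * w
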