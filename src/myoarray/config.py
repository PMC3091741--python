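"""Run configuration and the end-to-end pipeline.

:func:`run_pipeline` ties the stages together: read (or accept in-memory)
inputs, normalize/floor/filter, run the three contrasts, collapse to genes,
build pools A/D/E, subtract the direction-concordant time-confounded genes to
get Pool B, intersect to Pool C, and write every result table plus a Venn
summary JSON, a heat-map TSV for Pool B at 35 days, and a run manifest with
parameter values and input checksums.  Outputs are a pure function of the
inputs.

Configuration may come from a flat ``key = value`` text file mirroring the
CLI flags; explicit CLI flags override file values.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

from . import diffexpr, heatmap, pools
from .exceptions import ValidationError
from .expression_io import (
    ExpressionMatrix,
    ProbeAnnotation,
    SampleDesign,
    read_annotation,
    read_design,
    read_expression_matrix,
    write_table,
)
from .preprocess import PreprocessParams, preprocess

log = logging.getLogger("myoarray")


@dataclass(frozen=True)
class PipelineConfig:
    """Paths, thresholds and flags of one pipeline run.

    Defaults reproduce the standard analysis settings: floor 10, 20% / 1.5-
    fold variability filter, drug contrasts at alpha 0.05, time contrast at
    alpha 0.01, no multiple-testing correction, heat-map written.
    """

    matrix_path: str | None = None
    design_path: str | None = None
    annotation_path: str | None = None
    output_dir: str = "results"
    floor_value: float = 10.0
    min_fraction: float = 0.20
    fold_threshold: float = 1.5
    alpha_nan: float = 0.05
    alpha_time: float = 0.01
    apply_bh: bool = False
    write_heatmap: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for a in (self.alpha_nan, self.alpha_time):
            if not 0 < a < 1:
                raise ValidationError("alphas must lie in (0, 1)")

    def preprocess_params(self) -> PreprocessParams:
        return PreprocessParams(
            floor_value=self.floor_value,
            min_fraction=self.min_fraction,
            fold_threshold=self.fold_threshold,
        )

    def contrasts(self) -> list[diffexpr.Contrast]:
        return [
            replace(diffexpr.NAN7, alpha=self.alpha_nan),
            replace(diffexpr.NAN35, alpha=self.alpha_nan),
            replace(diffexpr.TIME, alpha=self.alpha_time),
        ]


_BOOL_FIELDS = {"apply_bh", "write_heatmap"}
_INT_FIELDS = {"seed"}
_FLOAT_FIELDS = {"floor_value", "min_fraction", "fold_threshold",
                 "alpha_nan", "alpha_time"}


def load_config(path, overrides: dict | None = None) -> PipelineConfig:
    """Parse a flat ``key = value`` config file; ``overrides`` win."""
    values: dict = {}
    known = {f.name for f in fields(PipelineConfig)}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValidationError(f"{path}:{lineno}: expected 'key = value'")
        key, _, raw = line.partition("=")
        key, raw = key.strip(), raw.strip()
        if key not in known:
            raise ValidationError(f"{path}:{lineno}: unknown setting {key!r}")
        values[key] = _coerce(key, raw)
    if overrides:
        values.update({k: v for k, v in overrides.items() if v is not None})
    return PipelineConfig(**values)


def _coerce(key: str, raw: str):
    if key in _BOOL_FIELDS:
        if raw.lower() in ("1", "true", "yes", "on"):
            return True
        if raw.lower() in ("0", "false", "no", "off"):
            return False
        raise ValidationError(f"{key}: expected a boolean, got {raw!r}")
    if key in _INT_FIELDS:
        return int(raw)
    if key in _FLOAT_FIELDS:
        return float(raw)
    return raw


@dataclass
class PipelineResult:
    """In-memory bundle of everything one run produced."""

    de_tables: dict          # contrast name -> probe-level DETable
    gene_tables: dict        # contrast name -> gene-level DETable
    pools: dict              # 'A'|'B'|'C'|'D'|'E'|'removed' -> GenePool
    venn: pools.VennSummary
    heatmap: object | None = None
    kept_probes: list = field(default_factory=list)
    excluded_probes: list = field(default_factory=list)
    output_dir: Path | None = None


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(
    config: PipelineConfig,
    matrix: ExpressionMatrix | None = None,
    design: SampleDesign | None = None,
    annotation: ProbeAnnotation | None = None,
    write: bool = True,
) -> PipelineResult:
    """Execute the full analysis; see the module docstring for the stages.

    Inputs may be passed in memory (as the simulator produces them) or read
    from the paths in ``config``.
    """
    checksums = {}
    if matrix is None:
        if config.matrix_path is None:
            raise ValidationError("no expression matrix given (path or object)")
        log.info("reading expression matrix from %s", config.matrix_path)
        matrix = read_expression_matrix(config.matrix_path)
        checksums["matrix"] = _sha256(config.matrix_path)
    if design is None:
        if config.design_path is None:
            raise ValidationError("no sample design given (path or object)")
        design = read_design(config.design_path)
        checksums["design"] = _sha256(config.design_path)
    if annotation is None:
        if config.annotation_path is None:
            raise ValidationError(
                "no probe annotation given; gene-level analysis refuses to "
                "run without gene symbols"
            )
        annotation = read_annotation(config.annotation_path)
        checksums["annotation"] = _sha256(config.annotation_path)
    if annotation.n_known == 0:
        raise ValidationError("annotation assigns no gene symbols; gene-level "
                              "analysis cannot run")
    design.check_against(matrix)

    log.info("preprocessing %d probes x %d arrays", *matrix.shape)
    filtered, kept, excluded = preprocess(matrix, config.preprocess_params())
    log.info("variability filter kept %d / %d probes", len(kept),
             matrix.shape[0])

    de_tables, gene_tables, pool_objs = {}, {}, {}
    for contrast in config.contrasts():
        de = diffexpr.run_contrast(filtered, design, contrast)
        if config.apply_bh:
            de = diffexpr.benjamini_hochberg(de, contrast.alpha)
        de_tables[contrast.name] = de
        gene_tables[contrast.name] = diffexpr.collapse_to_genes(de, annotation)
        log.info("contrast %s: %d significant probes, %d significant genes",
                 contrast.name, int(de["significant"].sum()),
                 int(gene_tables[contrast.name]["significant"].sum()))

    pool_objs["A"] = pools.build_pool(gene_tables["NAN7"], "A")
    pool_objs["D"] = pools.build_pool(gene_tables["NAN35"], "D")
    pool_objs["E"] = pools.build_pool(gene_tables["TIME"], "E")
    pool_objs["B"], pool_objs["removed"] = pools.concordant_subtract(
        pool_objs["D"], pool_objs["E"]
    )
    pool_objs["C"] = pools.intersect_pools(pool_objs["A"], pool_objs["B"])
    venn = pools.venn_summary(
        pool_objs["A"], pool_objs["B"], pool_objs["C"],
        pool_objs["D"], pool_objs["E"], pool_objs["removed"],
    )
    log.info("pool sizes: %s", venn.sizes)

    hm = None
    if config.write_heatmap and len(pool_objs["B"]):
        genes_b = pool_objs["B"].members.index
        rep_probes = gene_tables["NAN35"].loc[genes_b, "probe_id"].tolist()
        hm = heatmap.heatmap_matrix(filtered, design, rep_probes, timepoint=35)
        hm.index = list(genes_b)

    result = PipelineResult(
        de_tables=de_tables, gene_tables=gene_tables, pools=pool_objs,
        venn=venn, heatmap=hm, kept_probes=kept, excluded_probes=excluded,
    )
    if write:
        result.output_dir = _write_outputs(result, config, checksums)
    return result


def _write_outputs(result: PipelineResult, config: PipelineConfig,
                   checksums: dict) -> Path:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, de in result.de_tables.items():
        write_table(de, out / f"de_{name}.tsv")
    for name, de in result.gene_tables.items():
        write_table(de, out / f"genes_{name}.tsv")
    for name, pool in result.pools.items():
        label = "removed" if name == "removed" else f"pool_{name}"
        write_table(pool.members.sort_index(), out / f"{label}.tsv")
    (out / "venn.json").write_text(result.venn.to_json() + "\n")
    if result.heatmap is not None:
        write_table(result.heatmap, out / "heatmap_35d.tsv",
                    index_label="gene_symbol")
    # output_dir is where results land, not a parameter of the analysis;
    # leaving it out keeps two runs into different directories file-identical
    manifest = {
        "parameters": {
            f.name: getattr(config, f.name) for f in fields(PipelineConfig)
            if f.name != "output_dir"
        },
        "input_sha256": checksums,
        "n_probes_kept": len(result.kept_probes),
        "pool_sizes": result.venn.sizes,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True) + "\n")
    return out
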