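"""Gene-pool construction, direction-concordant subtraction, intersection.

The analysis compares drug-regulated gene sets between the two timepoints:

* Pool A — genes regulated by the drug at 7 days (alpha 0.05),
* Pool D — genes regulated by the drug at 35 days, before any correction,
* Pool E — genes changed by time alone (35 vs 7 days in vehicle, alpha 0.01),
* Pool B — Pool D minus genes that are also in Pool E *with the same
  direction of change* (those could reflect the passage of time rather than
  drug action; opposite-direction overlaps stay),
* Pool C — Pool A ∩ Pool B, the genes regulated at both timepoints.

Pools are keyed by upper-cased gene symbol and satisfy exact set identities:
B ∪ removed = D, B ∩ removed = ∅, C = A ∩ B.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import pandas as pd

from .exceptions import ComputationError, ValidationError

UP = "up"
DOWN = "down"


@dataclass(frozen=True)
class GenePool:
    """A named set of genes with per-gene direction, p-value and fold change."""

    name: str
    members: pd.DataFrame = field()  # index: gene_symbol; columns:
    #   direction, p_value, fold_change

    def __post_init__(self) -> None:
        m = self.members
        if m.index.duplicated().any():
            dup = m.index[m.index.duplicated()][0]
            raise ValidationError(f"pool {self.name}: gene {dup!r} listed twice")
        if len(m) and not m["direction"].isin([UP, DOWN]).all():
            raise ValidationError(f"pool {self.name}: bad direction labels")

    def __len__(self) -> int:
        return len(self.members)

    @property
    def genes(self) -> set[str]:
        return set(self.members.index)

    def direction_of(self, gene: str) -> str:
        return str(self.members.at[gene, "direction"])

    @classmethod
    def empty(cls, name: str) -> "GenePool":
        return cls(name, _empty_members())


def _empty_members() -> pd.DataFrame:
    return pd.DataFrame(
        {"direction": pd.Series(dtype=str),
         "p_value": pd.Series(dtype=float),
         "fold_change": pd.Series(dtype=float)}
    ).rename_axis("gene_symbol")


def build_pool(de_genes: pd.DataFrame, name: str) -> GenePool:
    """Build a pool from a gene-level DETable: its significant genes.

    Direction is the sign of the signed fold change (``up`` for positive).
    """
    if "significant" not in de_genes.columns:
        raise ValidationError("expected a gene-level DETable with a "
                              "'significant' column")
    sig = de_genes[de_genes["significant"]]
    members = pd.DataFrame(
        {
            "direction": [UP if fc >= 0 else DOWN for fc in sig["fold_change"]],
            "p_value": sig["p_value"].to_numpy(),
            "fold_change": sig["fold_change"].to_numpy(),
        },
        index=sig.index.rename("gene_symbol"),
    )
    return GenePool(name, members)


def concordant_subtract(pool_d: GenePool, pool_e: GenePool,
                        name: str = "B") -> tuple[GenePool, GenePool]:
    """Remove from D the genes also present in E with the same direction.

    Returns ``(pool_b, removed)``.  A gene in both pools with *opposite*
    directions is retained in B: its drug response cannot be explained by
    the time trend.
    """
    d = pool_d.members
    in_both = d.index.intersection(pool_e.members.index)
    same_dir = [
        g for g in in_both
        if pool_d.direction_of(g) == pool_e.direction_of(g)
    ]
    removed = GenePool("removed", d.loc[d.index.isin(same_dir)])
    pool_b = GenePool(name, d.loc[~d.index.isin(same_dir)])
    return pool_b, removed


def intersect_pools(pool_a: GenePool, pool_b: GenePool,
                    name: str = "C") -> GenePool:
    """Genes present in both pools, carrying both pools' statistics.

    The member table keeps A's direction/p/fold columns and adds B's as
    ``direction_b``, ``p_value_b``, ``fold_change_b`` for reporting.
    """
    common = pool_a.members.index.intersection(pool_b.members.index)
    members = pool_a.members.loc[common].copy()
    other = pool_b.members.loc[common]
    members["direction_b"] = other["direction"]
    members["p_value_b"] = other["p_value"]
    members["fold_change_b"] = other["fold_change"]
    return GenePool(name, members)


@dataclass(frozen=True)
class VennSummary:
    """Sizes and membership of pools A-E plus the removed concordant set."""

    sizes: dict[str, int]
    members: dict[str, list[str]]

    def to_json(self, indent: int = 2) -> str:
        payload = dict(self.sizes)
        payload["members"] = self.members
        return json.dumps(payload, indent=indent, sort_keys=True)


def venn_summary(
    pool_a: GenePool,
    pool_b: GenePool,
    pool_c: GenePool,
    pool_d: GenePool,
    pool_e: GenePool,
    removed: GenePool,
) -> VennSummary:
    """Summarize pool sizes, checking the internal set identities."""
    if not pool_c.genes <= pool_a.genes or not pool_c.genes <= pool_b.genes:
        raise ComputationError("inconsistent pools: C must be a subset of "
                               "both A and B")
    if pool_c.genes != (pool_a.genes & pool_b.genes):
        raise ComputationError("inconsistent pools: C != A ∩ B")
    if len(pool_b) + len(removed) != len(pool_d):
        raise ComputationError("inconsistent pools: |B| + |removed| != |D|")
    pools = {"A": pool_a, "B": pool_b, "C": pool_c,
             "D": pool_d, "E": pool_e, "removed": removed}
    return VennSummary(
        sizes={k: len(v) for k, v in pools.items()},
        members={k: sorted(v.genes) for k, v in pools.items()},
    )


def pool_from_records(name: str, records) -> GenePool:
    """Convenience constructor from (gene, direction[, p, fold]) tuples."""
    rows = []
    for rec in records:
        gene, direction = rec[0], rec[1]
        p = rec[2] if len(rec) > 2 else float("nan")
        fc = rec[3] if len(rec) > 3 else (1.5 if direction == UP else -1.5)
        rows.append((str(gene).upper(), direction, p, fc))
    if not rows:
        return GenePool.empty(name)
    frame = pd.DataFrame(
        rows, columns=["gene_symbol", "direction", "p_value", "fold_change"]
    ).set_index("gene_symbol")
    return GenePool(name, frame)
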