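"""Gene-set filtering, intersection, and enrichment logic.

Fold changes are mutant/control (or IP/control) expression ratios.  A gene
"up in the mutant" (fold >= threshold) is one whose expression the wild-type
factor suppresses, i.e. it is factor-DOWNregulated; a gene "down in the
mutant" (fold <= 1/threshold) is factor-UPregulated.  Significance columns
are treated generically (FDR or p, depending on the upstream pipeline).

Thresholds follow the usual convention here: fold-change cut inclusive
(>= 2, and symmetrically <= 1/2), significance cut strict (< 0.1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

DE_COLUMNS = ["gene_id", "fold_change", "significance"]
RIP_COLUMNS = ["gene_id", "line", "fold_change", "significance"]


@dataclass
class GeneSetResult:
    label: str
    genes: frozenset[str]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.genes)


def _validate_fold_changes(table: pd.DataFrame, label: str) -> pd.DataFrame:
    bad = table["fold_change"] <= 0
    if bad.any():
        warnings.warn(
            f"{label}: dropped {int(bad.sum())} rows with non-positive fold "
            "change", stacklevel=3,
        )
        table = table[~bad]
    return table


def filter_de(table: pd.DataFrame, min_fc: float = 2.0,
              max_sig: float = 0.1, label: str = "DE table"
              ) -> tuple[set[str], set[str]]:
    """Split a differential-expression table into (up_in_mutant,
    down_in_mutant) gene sets: fold >= min_fc (resp. <= 1/min_fc) with
    significance < max_sig."""
    table = _validate_fold_changes(table[DE_COLUMNS].copy(), label)
    sig = table["significance"] < max_sig
    up = set(table.loc[sig & (table["fold_change"] >= min_fc), "gene_id"])
    down = set(table.loc[sig & (table["fold_change"] <= 1.0 / min_fc),
                         "gene_id"])
    return up, down


def consensus(set_pairs: list[tuple[set[str], set[str]]]
              ) -> tuple[set[str], set[str]]:
    """Direction-wise intersection of (up, down) gene-set pairs from two or
    more sources."""
    if len(set_pairs) < 2:
        raise ValueError("consensus requires at least two sources")
    up = set.intersection(*(set(u) for u, _ in set_pairs))
    down = set.intersection(*(set(d) for _, d in set_pairs))
    return up, down


def select_sars(rip_tables: dict[str, pd.DataFrame], min_fc: float = 2.0,
                max_sig: float = 0.1, lines: tuple[str, str] = ("line1", "line2")
                ) -> GeneSetResult:
    """Immunoprecipitation-enriched transcript selection.

    Each method's table is long-format (gene_id, line, fold_change,
    significance) with one row per IP line vs control.  A gene passes a
    method when it meets fold >= min_fc and significance < max_sig in BOTH
    lines; genes missing a line are excluded from that method.  The final
    set is the intersection across methods.
    """
    per_method: dict[str, set[str]] = {}
    for method in sorted(rip_tables):
        table = _validate_fold_changes(
            rip_tables[method][RIP_COLUMNS].copy(), method
        )
        passing = table[
            (table["fold_change"] >= min_fc)
            & (table["significance"] < max_sig)
        ]
        by_gene = passing.groupby("gene_id")["line"].agg(set)
        per_method[method] = {
            g for g, seen in by_gene.items() if set(lines) <= seen
        }
    genes = (set.intersection(*per_method.values())
             if per_method else set())
    return GeneSetResult(
        label="bound_transcripts",
        genes=frozenset(genes),
        provenance={
            "min_fc": min_fc, "max_sig": max_sig,
            "per_method_sizes": {m: len(s) for m, s in per_method.items()},
        },
    )


def fisher_overlap(set_a: set[str], set_b: set[str], universe: set[str]
                   ) -> tuple[float, float]:
    """Two-sided Fisher exact test of the overlap between two gene sets
    within a universe. Returns (odds_ratio, p); odds ratio is nan when a
    margin is empty."""
    if not universe:
        raise ValueError("empty universe")
    a, b = set_a & universe, set_b & universe
    n11 = len(a & b)
    n12 = len(a - b)
    n21 = len(b - a)
    n22 = len(universe) - n11 - n12 - n21
    odds, p = stats.fisher_exact([[n11, n12], [n21, n22]],
                                 alternative="two-sided")
    return float(odds), float(p)


def term_enrichment(gene_set: set[str], term_map: pd.DataFrame,
                    universe: set[str]) -> pd.DataFrame:
    """Hypergeometric term over-representation.

    `term_map` has columns (gene_id, term).  For each term with K annotated
    genes in the universe and k of them in the n-gene query set:
    expected = n*K/N, fold = actual/expected, p = upper-tail hypergeometric
    P(X >= k).  Terms absent from the universe are skipped.
    """
    gene_set = set(gene_set) & universe
    n, N = len(gene_set), len(universe)
    rows = []
    for term, genes in term_map.groupby("term")["gene_id"]:
        term_genes = set(genes) & universe
        K = len(term_genes)
        if K == 0:
            continue
        k = len(term_genes & gene_set)
        expected = n * K / N
        rows.append({
            "term": term, "actual": k, "expected": expected,
            "fold": k / expected if expected > 0 else float("nan"),
            "p_value": float(stats.hypergeom.sf(k - 1, N, K, n)),
        })
    df = pd.DataFrame(rows, columns=["term", "actual", "expected", "fold",
                                     "p_value"])
    return df.sort_values("p_value", kind="stable").reset_index(drop=True)


def intronless_fraction(gene_set: set[str], intronless_genes: set[str]
                        ) -> float:
    """Percentage of a gene set annotated as single-exon (intronless)."""
    if not gene_set:
        raise ValueError("empty gene set")
    return 100.0 * len(set(gene_set) & set(intronless_genes)) / len(gene_set)


def read_gene_table(path: str, columns: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def read_gene_list(path: str) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def write_gene_list(genes: set[str], path: str) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(g + "\n")
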