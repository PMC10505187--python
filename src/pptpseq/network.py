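"""Signed TF->promoter perturbation-response networks and binding analysis.

A knockdown that *raises* a promoter's activity implies the TF normally
represses it, and a knockdown that lowers activity implies activation; each
non-ns differential call therefore becomes one signed edge keyed by the
target TF gene. Utilities detect autoregulation (a TF regulating its own
promoter), tabulate edge overlap across growth conditions, normalize DAP-seq
style binding strengths per TF and per promoter, and compare features of
binding sites whose TF does versus does not regulate the bound promoter
(Wilcoxon rank-sum, Benjamini-Hochberg adjusted across features).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .data_io import LibraryAnnotation
from .diffcall import DifferentialCall

__all__ = [
    "RegulatoryEdge",
    "build_network",
    "autoregulation",
    "condition_overlap",
    "relative_binding",
    "regulating_vs_nonregulating",
]


@dataclass(frozen=True)
class RegulatoryEdge:
    tf: str
    promoter_id: str
    sign: str  # "activation" | "repression"
    condition: str
    fold_vs_control: float
    q: float


def build_network(
    calls: Iterable[DifferentialCall], condition: str = ""
) -> list[RegulatoryEdge]:
    """One signed edge per non-ns call.

    Upregulation under knockdown maps to repression by the TF, downregulation
    to activation. TFs named as two genes (heteromeric regulators, e.g.
    "ihfA;ihfB") yield one edge per gene.
    """
    edges: list[RegulatoryEdge] = []
    for c in calls:
        if c.call not in {"up", "down"}:
            continue
        sign = "repression" if c.call == "up" else "activation"
        for gene in str(c.target_tf).split(";"):
            gene = gene.strip()
            if gene:
                edges.append(
                    RegulatoryEdge(gene, c.promoter_id, sign, condition, c.fold_vs_control, c.q)
                )
    return edges


def autoregulation(
    edges: Iterable[RegulatoryEdge], library: LibraryAnnotation
) -> list[RegulatoryEdge]:
    """Edges where the regulating TF is the promoter's own gene product."""
    own_tf = dict(
        zip(
            library.promoters["promoter_id"],
            library.promoters["tf_gene_of_promoter"].fillna(""),
        )
    )
    return [e for e in edges if e.tf and own_tf.get(e.promoter_id, "") == e.tf]


def condition_overlap(
    edge_sets: Mapping[str, Iterable[RegulatoryEdge]]
) -> pd.DataFrame:
    """Venn-partition counts of signed edges across conditions.

    Each (tf, promoter, sign) tuple is assigned to exactly one membership
    pattern (the subset of conditions containing it); returns counts per
    pattern and sign. Patterns are "&"-joined sorted condition labels.
    """
    if len(edge_sets) < 2:
        raise ValueError("need at least two conditions to compare")
    keys: dict[str, set[tuple[str, str, str]]] = {
        cond: {(e.tf, e.promoter_id, e.sign) for e in edges}
        for cond, edges in edge_sets.items()
    }
    all_edges = set().union(*keys.values())
    rows = []
    conds = sorted(keys)
    for r in range(1, len(conds) + 1):
        for subset in combinations(conds, r):
            inside = set(subset)
            members = {
                e
                for e in all_edges
                if all(e in keys[c] for c in subset)
                and all(e not in keys[c] for c in conds if c not in inside)
            }
            for sign in ("activation", "repression"):
                rows.append(
                    ("&".join(subset), sign, sum(1 for e in members if e[2] == sign))
                )
    return pd.DataFrame(rows, columns=["membership_pattern", "sign", "count"])


def relative_binding(sites: pd.DataFrame, known_promoters: set[str] | None = None) -> pd.DataFrame:
    """Normalize binding strengths per TF and per promoter.

    Keeps the single strongest site per (tf, promoter), then computes
    fold_enrichment divided by the TF's maximum (relative strength per TF)
    and by the promoter's strongest bound TF (relative strength per
    promoter). The TSS-relative center is the midpoint of the retained
    0-based half-open interval minus the TSS position (negative upstream).
    Sites on promoters absent from ``known_promoters`` are dropped.
    """
    df = sites.copy()
    if known_promoters is not None:
        unknown = ~df["promoter_id"].isin(known_promoters)
        if unknown.any():
            import warnings

            warnings.warn(
                f"dropping {int(unknown.sum())} site(s) on unknown promoters",
                stacklevel=2,
            )
            df = df.loc[~unknown]
    if df.empty:
        return df.assign(
            tss_relative_center=pd.Series(dtype=float),
            rel_strength_per_tf=pd.Series(dtype=float),
            rel_strength_per_promoter=pd.Series(dtype=float),
        )
    if (df["fold_enrichment"] <= 0).any():
        raise ValueError("fold_enrichment must be positive")
    best = df.loc[
        df.groupby(["tf", "promoter_id"])["fold_enrichment"].idxmax()
    ].copy()
    best["tss_relative_center"] = (
        (best["site_start"] + best["site_end"]) / 2.0 - best["tss_position"]
    )
    best["rel_strength_per_tf"] = best["fold_enrichment"] / best.groupby("tf")[
        "fold_enrichment"
    ].transform("max")
    best["rel_strength_per_promoter"] = best["fold_enrichment"] / best.groupby(
        "promoter_id"
    )["fold_enrichment"].transform("max")
    return best.reset_index(drop=True)


DEFAULT_FEATURES = (
    "tss_relative_center",
    "rel_strength_per_tf",
    "rel_strength_per_promoter",
)


def regulating_vs_nonregulating(
    sites: pd.DataFrame,
    edges: Iterable[RegulatoryEdge],
    features: Sequence[str] | None = None,
    min_group: int = 3,
) -> pd.DataFrame:
    """Compare binding-site features between regulating and non-regulating TFs.

    A site is "regulating" when its (tf, promoter) pair carries a network
    edge. Each feature (binding position, relative strengths, and any extra
    numeric column such as TF concentration) is tested by a two-sided
    Wilcoxon rank-sum test; p-values are BH-adjusted across features. Groups
    smaller than ``min_group`` yield NA for that feature.
    """
    features = list(features) if features is not None else [
        f for f in DEFAULT_FEATURES if f in sites.columns
    ]
    edge_keys = {(e.tf, e.promoter_id) for e in edges}
    annotated = sites.copy()
    annotated["regulating"] = [
        (tf, pr) in edge_keys
        for tf, pr in zip(annotated["tf"], annotated["promoter_id"])
    ]
    rows = []
    for feat in features:
        vals = annotated[[feat, "regulating"]].dropna()
        a = vals.loc[vals["regulating"], feat].to_numpy(dtype=float)
        b = vals.loc[~vals["regulating"], feat].to_numpy(dtype=float)
        if len(a) < min_group or len(b) < min_group:
            rows.append((feat, len(a), len(b), np.nan, np.nan))
            continue
        stat, p = mannwhitneyu(a, b, alternative="two-sided")
        rows.append((feat, len(a), len(b), float(stat), float(p)))
    out = pd.DataFrame(
        rows, columns=["feature", "n_regulating", "n_nonregulating", "statistic", "p"]
    )
    tested = out["p"].notna()
    out["p_adjusted"] = np.nan
    if tested.any():
        out.loc[tested, "p_adjusted"] = multipletests(
            out.loc[tested, "p"], method="fdr_bh"
        )[1]
    out.attrs["annotated_sites"] = annotated
    return out
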