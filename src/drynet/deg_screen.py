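"""Drought-responsive gene screen across multiple microarray experiment sets.

Per experiment set, every gene is tested for differential expression between
stress and control replicates (two-sample t-test on log2 values) combined
with a fold-change cutoff; a gene is called *responsive* when it passes in a
minimum number of experiment sets, which suppresses set-specific artifacts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

CONTROL = "control"
STRESS = "stress"


@dataclass
class ExpressionSet:
    """Log2 expression matrix of one experiment set plus its sample design.

    matrix
        genes x samples DataFrame of normalized log2 intensities.
    design
        One row per sample (index = sample id) with columns ``set``,
        ``condition`` (``control``/``stress``) and ``replicate``.
    """

    matrix: pd.DataFrame
    design: pd.DataFrame
    set_id: str

    def __post_init__(self) -> None:
        if list(self.matrix.columns) != list(self.design.index):
            raise ValueError(f"{self.set_id}: matrix columns and design rows differ")
        bad = set(self.design["condition"]) - {CONTROL, STRESS}
        if bad:
            raise ValueError(f"{self.set_id}: unknown conditions {bad}")
        if self.matrix.index.has_duplicates or self.matrix.index.isna().any():
            raise ValueError(f"{self.set_id}: gene ids must be unique and non-missing")

    def samples(self, condition: str) -> pd.DataFrame:
        keep = self.design.index[self.design["condition"] == condition]
        return self.matrix[keep]

    def to_tsv(self, expr_path, design_path) -> None:
        self.matrix.to_csv(expr_path, sep="\t", index_label="gene")
        self.design.to_csv(design_path, sep="\t", index_label="sample")

    @classmethod
    def from_tsv(cls, expr_path, design_path, set_id: str | None = None) -> "ExpressionSet":
        matrix = pd.read_csv(expr_path, sep="\t", index_col="gene")
        design = pd.read_csv(design_path, sep="\t", index_col="sample")
        sid = set_id or str(design["set"].iloc[0])
        design = design[design["set"] == sid] if design["set"].nunique() > 1 else design
        return cls(matrix=matrix[list(design.index)], design=design, set_id=sid)


def test_differential(
    eset: ExpressionSet,
    alpha: float = 0.05,
    fold_cutoff: float = 2.0,
    equal_var: bool = False,
    linear_fold: bool = False,
) -> pd.DataFrame:
    """Per-gene stress-vs-control differential test for one experiment set.

    The fold change is ``mean(stress) - mean(control)`` on the log2 scale
    (or, with ``linear_fold=True``, the log2 ratio of linear-scale means of
    the replicate intensities). The p-value comes from a two-sample t-test
    on the log2 replicate values; Welch's unequal-variance form is the
    default, ``equal_var=True`` selects the pooled-variance variant.

    A gene passes when ``p < alpha`` and ``|fold change| >= fold_cutoff``
    (the fold boundary is inclusive: a gene changing exactly
    ``fold_cutoff``-fold with a significant p passes). Genes with fewer
    than two usable replicates in either condition are flagged untestable
    and excluded from the pass/fail decision.

    Returns a DataFrame indexed by gene with columns ``log2fc``, ``p``,
    ``passed`` and ``testable``.
    """
    ctrl = eset.samples(CONTROL).to_numpy(dtype=float)
    strs = eset.samples(STRESS).to_numpy(dtype=float)
    n_ctrl = np.sum(~np.isnan(ctrl), axis=1)
    n_strs = np.sum(~np.isnan(strs), axis=1)
    testable = (n_ctrl >= 2) & (n_strs >= 2)
    if not testable.all():
        logger.warning(
            "%s: %d genes untestable (<2 replicates in a condition), excluded",
            eset.set_id, int((~testable).sum()),
        )

    if linear_fold:
        with np.errstate(invalid="ignore"):
            log2fc = np.log2(np.nanmean(2.0 ** strs, axis=1)) - np.log2(
                np.nanmean(2.0 ** ctrl, axis=1)
            )
    else:
        log2fc = np.nanmean(strs, axis=1) - np.nanmean(ctrl, axis=1)

    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(
            strs, ctrl, axis=1, equal_var=equal_var, nan_policy="omit"
        )
    p = np.asarray(res.pvalue, dtype=float)

    # identical zero-variance groups give 0/0 -> NaN; such genes cannot pass
    passed = testable & (p < alpha) & (np.abs(log2fc) >= np.log2(fold_cutoff))
    out = pd.DataFrame(
        {
            "log2fc": np.where(testable, log2fc, np.nan),
            "p": np.where(testable, p, np.nan),
            "passed": passed,
            "testable": testable,
        },
        index=eset.matrix.index,
    )
    return out


def cross_set_filter(
    tables: Mapping[str, pd.DataFrame] | Sequence[tuple[str, pd.DataFrame]],
    min_sets: int = 2,
) -> pd.DataFrame:
    """Combine per-set differential tables into the responsive-gene call.

    A gene is *responsive* when it passed the per-set screen in at least
    ``min_sets`` experiment sets; counting runs only over sets where the
    gene is present and testable (absences are logged, not failed). Per-set
    fold changes and p-values are preserved in columns named
    ``log2fc.<set>``, ``p.<set>``, ``pass.<set>`` for downstream module
    statistics.
    """
    items = list(tables.items()) if isinstance(tables, Mapping) else list(tables)
    if len(items) < min_sets:
        raise ValueError(f"need at least min_sets={min_sets} experiment sets, got {len(items)}")
    genes = sorted(set().union(*(t.index for _, t in items)))
    out = pd.DataFrame(index=pd.Index(genes, name="gene"))
    n_passed = pd.Series(0, index=out.index)
    for sid, t in items:
        missing = len(genes) - len(t.index)
        if missing:
            logger.info("set %s: %d genes absent, counted over present sets only", sid, missing)
        t = t.reindex(out.index)
        out[f"log2fc.{sid}"] = t["log2fc"]
        out[f"p.{sid}"] = t["p"]
        out[f"pass.{sid}"] = t["passed"].notna() & (t["passed"] == True)  # noqa: E712
        n_passed += out[f"pass.{sid}"].astype(int)
    out["n_sets_passed"] = n_passed
    out["responsive"] = n_passed >= min_sets
    return out


def screen(
    esets: Iterable[ExpressionSet],
    alpha: float = 0.05,
    fold_cutoff: float = 2.0,
    min_sets: int = 2,
    equal_var: bool = False,
    linear_fold: bool = False,
) -> pd.DataFrame:
    """Convenience wrapper: per-set tests followed by the cross-set filter."""
    tables = [
        (e.set_id, test_differential(e, alpha, fold_cutoff, equal_var, linear_fold))
        for e in esets
    ]
    return cross_set_filter(tables, min_sets=min_sets)
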