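"""Relative expression from replicated qPCR Ct tables (Livak 2^-ddCt),
hormone time-course response classification, and heatmap matrix prep.

Per replicate r, dCt_r = Ct(target, r) - Ct(reference, r), replicates
paired by index; per sample the mean and sd of dCt are taken, then
ddCt = mean dCt(sample) - mean dCt(calibrator) and fold = 2^-ddCt, with the
replicate dispersion propagated on the dCt scale (fold_range =
2^-(ddCt +/- sd)). A gene is called hormone-responsive when, at some time
point after treatment, a two-sided Welch test on replicate dCt against the
0 h baseline is significant and the fold change passes a cutoff; the paper
behind this workflow states no test, so the Welch-plus-2-fold rule is a
documented choice of this package.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CtTable", "RelativeExpression", "GaResponse",
    "relative_expression_ddct", "delta_ct_replicates",
    "ga_response_classify", "tissue_heatmap_matrix",
]


class DesignError(ValueError):
    """Ct table or design violates its contract."""


@dataclass
class CtTable:
    """Replicated Ct records plus the reference gene and calibrator sample.

    ``data`` columns: sample, gene, replicate, ct.
    """

    data: pd.DataFrame
    reference_gene: str
    calibrator_sample: str

    def __post_init__(self) -> None:
        required = {"sample", "gene", "replicate", "ct"}
        if not required.issubset(self.data.columns):
            raise DesignError(f"Ct table needs columns {sorted(required)}")
        samples = set(self.data["sample"])
        if self.calibrator_sample not in samples:
            raise DesignError(
                f"calibrator sample {self.calibrator_sample!r} absent from table"
            )
        counts = self.data.groupby(["sample", "gene"]).size()
        low = counts[counts < 2]
        if not low.empty:
            s, g = low.index[0]
            raise DesignError(
                f"fewer than 2 replicates for gene {g!r} in sample {s!r}"
            )
        for s in samples:
            genes = set(self.data.loc[self.data["sample"] == s, "gene"])
            if self.reference_gene not in genes:
                raise DesignError(
                    f"reference gene {self.reference_gene!r} missing in "
                    f"sample {s!r}"
                )

    @property
    def samples(self) -> list[str]:
        return sorted(set(self.data["sample"]))

    @property
    def target_genes(self) -> list[str]:
        return sorted(set(self.data["gene"]) - {self.reference_gene})


@dataclass(frozen=True)
class RelativeExpression:
    sample_id: str
    gene_id: str
    fold: float
    delta_ct_mean: float
    delta_ct_sd: float
    fold_range: tuple[float, float]


def delta_ct_replicates(tbl: CtTable) -> pd.DataFrame:
    """Per-replicate dCt (target minus reference, paired by replicate
    index) for every gene and sample; columns sample, gene, replicate,
    delta_ct."""
    ref = tbl.data[tbl.data["gene"] == tbl.reference_gene].set_index(
        ["sample", "replicate"])["ct"]
    rows = []
    for (sample, gene), grp in tbl.data.groupby(["sample", "gene"]):
        for _, rec in grp.iterrows():
            key = (sample, rec["replicate"])
            if key not in ref.index:
                raise DesignError(
                    f"no reference Ct for replicate {rec['replicate']} in "
                    f"sample {sample!r}"
                )
            rows.append({
                "sample": sample, "gene": gene,
                "replicate": rec["replicate"],
                "delta_ct": rec["ct"] - float(ref.loc[key]),
            })
    return pd.DataFrame(rows)


def relative_expression_ddct(tbl: CtTable) -> list[RelativeExpression]:
    """Livak 2^-ddCt relative expression for every gene and sample."""
    dct = delta_ct_replicates(tbl)
    stats_df = dct.groupby(["sample", "gene"])["delta_ct"].agg(
        ["mean", "std"]).reset_index()
    stats_df["std"] = stats_df["std"].fillna(0.0)
    cal = stats_df[stats_df["sample"] == tbl.calibrator_sample].set_index(
        "gene")["mean"]
    out: list[RelativeExpression] = []
    for rec in stats_df.itertuples():
        if rec.gene not in cal.index:
            raise DesignError(
                f"gene {rec.gene!r} absent from calibrator sample"
            )
        ddct = rec.mean - float(cal.loc[rec.gene])
        fold = 2.0 ** (-ddct)
        lo = 2.0 ** (-(ddct + rec.std))
        hi = 2.0 ** (-(ddct - rec.std))
        out.append(RelativeExpression(
            sample_id=rec.sample, gene_id=rec.gene, fold=fold,
            delta_ct_mean=rec.mean, delta_ct_sd=rec.std,
            fold_range=(lo, hi),
        ))
    return out


@dataclass(frozen=True)
class GaResponse:
    gene_id: str
    responsive: bool
    first_responsive_time: float | None
    per_time: dict = field(hash=False, default_factory=dict)


def ga_response_classify(gene_id: str,
                         delta_ct_by_time: dict[float, "np.ndarray | list[float]"],
                         alpha: float = 0.05,
                         fold_cut: float = 2.0) -> GaResponse:
    """Classify a hormone time course as responsive or not.

    ``delta_ct_by_time`` maps hours post-treatment to replicate dCt values;
    0 h must be present and is the calibrator. A time point responds when
    the Welch p-value (vs 0 h) is below ``alpha`` and the fold change is
    >= ``fold_cut`` or <= 1/``fold_cut``; the first responding time point
    is reported.
    """
    if 0 not in delta_ct_by_time and 0.0 not in delta_ct_by_time:
        raise DesignError("time course lacks the 0 HPT calibrator point")
    base = np.asarray(delta_ct_by_time[0], dtype=float)
    if base.size < 2:
        raise DesignError("need >= 2 replicates per time point")
    per_time: dict[float, dict] = {}
    first: float | None = None
    for t in sorted(delta_ct_by_time):
        if t == 0:
            continue
        vals = np.asarray(delta_ct_by_time[t], dtype=float)
        if vals.size < 2:
            raise DesignError("need >= 2 replicates per time point")
        fold = 2.0 ** (-(vals.mean() - base.mean()))
        # zero-variance comparisons yield NaN p, handled as not significant
        with np.errstate(divide="ignore", invalid="ignore"), \
                warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            _, p = stats.ttest_ind(vals, base, equal_var=False)
        p = float(p)
        significant = (not math.isnan(p)) and p < alpha
        passes_fold = fold >= fold_cut or fold <= 1.0 / fold_cut
        responds = significant and passes_fold
        per_time[t] = {"fold": fold, "p_value": p, "responds": responds}
        if responds and first is None:
            first = t
    return GaResponse(
        gene_id=gene_id, responsive=first is not None,
        first_responsive_time=first, per_time=per_time,
    )


def tissue_heatmap_matrix(expr: pd.DataFrame, pseudocount: float = 1.0
                          ) -> pd.DataFrame:
    """log2(value + pseudocount) heatmap matrix, row order preserved."""
    values = expr.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("expression values must be non-negative")
    return pd.DataFrame(
        np.log2(values + pseudocount), index=expr.index, columns=expr.columns
    )
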