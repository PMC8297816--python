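"""qPCR quantification: geNorm reference stability and Livak relative expression.

The quantification layer turns raw quantification cycles (Ct) into
relative expression. Reference-gene stability is ranked with the geNorm
M statistic (mean standard deviation of pairwise log2 expression ratios);
normalization uses the geometric mean of the selected references; relative
expression follows the 2^-ddCt method (or 2^-dCt without calibrator),
generalized to an arbitrary amplification efficiency E via E^-dCt.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CT_COLUMNS = ("sample_id", "species", "timepoint_h", "replicate", "gene", "ct")


@dataclass
class StabilityRanking:
    """geNorm output: per-gene M values and the iterative exclusion order.

    ``m_values`` are computed on the full candidate panel; lower M = more
    stable. ``exclusion_order`` lists genes in the order geNorm would drop
    them (least stable first, recomputing M each round) until two remain.
    """

    m_values: dict[str, float]
    exclusion_order: list[str]

    def to_json_dict(self) -> dict:
        return {"m_values": self.m_values, "exclusion_order": self.exclusion_order}


def _m_values(log_q: pd.DataFrame) -> pd.Series:
    """M_j = mean over k != j of SD across samples of log2(q_j / q_k)."""
    genes = log_q.columns
    m = {}
    for j in genes:
        sds = [
            (log_q[j] - log_q[k]).std(ddof=1) for k in genes if k != j
        ]
        m[j] = float(np.mean(sds))
    return pd.Series(m)


def genorm_m(quantities: pd.DataFrame) -> StabilityRanking:
    """Rank candidate reference genes by geNorm expression stability.

    ``quantities`` is a samples x genes matrix of relative quantities
    (any positive scale; per-gene scaling cancels in the ratios).
    """
    q = quantities.astype(float)
    if q.shape[1] < 2:
        raise ValueError("geNorm requires at least 2 candidate reference genes")
    if q.shape[0] < 2:
        raise ValueError("geNorm requires at least 2 samples")
    if (q <= 0).any().any() or q.isna().any().any():
        raise ValueError("all relative quantities must be positive and non-missing")
    log_q = np.log2(q)
    full_m = _m_values(log_q)
    exclusion: list[str] = []
    remaining = list(q.columns)
    while len(remaining) > 2:
        m = _m_values(log_q[remaining])
        # drop highest M; ties broken alphabetically for reproducibility
        worst = sorted(m.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
        exclusion.append(worst)
        remaining.remove(worst)
    return StabilityRanking(
        m_values={g: float(full_m[g]) for g in q.columns},
        exclusion_order=exclusion,
    )


def normalization_factor(
    ct_refs: pd.DataFrame,
    selected_refs: list[str],
    efficiency: float = 2.0,
) -> pd.Series:
    """Per-sample normalization factor from reference Cts.

    geNorm convention: each reference's relative quantity is
    E^(minCt - Ct) (so the best-expressed sample scores 1), and the
    factor is the geometric mean of the selected references' quantities.
    """
    if not selected_refs:
        raise ValueError("selected_refs must be non-empty")
    missing_cols = [g for g in selected_refs if g not in ct_refs.columns]
    if missing_cols:
        raise ValueError(f"reference genes absent from table: {missing_cols}")
    sub = ct_refs[selected_refs].astype(float)
    bad = sub.index[sub.isna().any(axis=1)]
    if len(bad):
        raise ValueError(f"missing reference Ct for samples: {list(bad)}")
    log2_e = np.log2(efficiency)
    log2_q = (sub.min(axis=0) - sub) * log2_e
    return np.exp2(log2_q.mean(axis=1))


def _delta_ct(wide_ct: pd.DataFrame, refs: list[str]) -> pd.DataFrame:
    """dCt per target gene: Ct_target - mean(Ct of references), per sample."""
    missing = [g for g in refs if g not in wide_ct.columns]
    if missing:
        raise ValueError(f"reference genes absent from table: {missing}")
    ref_mean = wide_ct[refs].mean(axis=1)
    bad = wide_ct.index[wide_ct[refs].isna().any(axis=1)]
    if len(bad):
        raise ValueError(f"missing reference Ct for samples: {list(bad)}")
    targets = [g for g in wide_ct.columns if g not in refs]
    return wide_ct[targets].sub(ref_mean, axis=0)


def relative_expression(
    ct_table: pd.DataFrame,
    refs: list[str],
    calibrator_timepoint: float | None = -96,
    mode: str = "ddct",
    efficiency: float = 2.0,
) -> pd.DataFrame:
    """Livak relative expression from a long-format Ct table.

    mode ``"ddct"``: E^-(dCt_sample - mean dCt over the calibrator
    samples), computed per species and per gene; the calibrator mean is
    taken on the dCt (log) scale, so the *geometric* mean of relative
    expression over calibrator samples is 1.
    mode ``"dct"``: E^-dCt, no calibrator (the heatmap/clustering scale).

    Missing Cts propagate as missing rel_expr. Returns a long table with
    columns ``sample_id, species, timepoint_h, replicate, gene,
    rel_expr, mode``.
    """
    if mode not in ("ddct", "dct"):
        raise ValueError(f"mode must be 'ddct' or 'dct', got {mode!r}")
    log2_e = np.log2(efficiency)
    out = []
    meta_cols = ["sample_id", "species", "timepoint_h", "replicate"]
    for species, sub in ct_table.groupby("species", sort=True):
        wide = sub.pivot(index="sample_id", columns="gene", values="ct")
        dct = _delta_ct(wide, refs)
        if mode == "ddct":
            if calibrator_timepoint is None:
                raise ValueError("ddct mode requires a calibrator timepoint")
            meta = sub[meta_cols].drop_duplicates().set_index("sample_id")
            cal_samples = meta.index[meta["timepoint_h"] == calibrator_timepoint]
            if len(cal_samples) == 0:
                raise ValueError(
                    f"no calibrator samples at timepoint {calibrator_timepoint} "
                    f"for species {species}"
                )
            cal_mean = dct.loc[cal_samples].mean(axis=0)
            absent = cal_mean.index[cal_mean.isna()]
            if len(absent):
                raise ValueError(
                    f"genes absent from calibrator samples: {list(absent)}"
                )
            dct = dct.sub(cal_mean, axis=1)
        rel = np.exp2(-dct * log2_e)
        long = rel.reset_index().melt(
            id_vars="sample_id", var_name="gene", value_name="rel_expr"
        )
        meta = sub[meta_cols].drop_duplicates()
        long = long.merge(meta, on="sample_id", how="left")
        long["mode"] = mode
        out.append(long)
    cols = meta_cols + ["gene", "rel_expr", "mode"]
    return (
        pd.concat(out, ignore_index=True)[cols]
        .sort_values(["species", "gene", "timepoint_h", "replicate"])
        .reset_index(drop=True)
    )


def reference_quantities(
    ct_table: pd.DataFrame, candidate_refs: list[str], efficiency: float = 2.0
) -> pd.DataFrame:
    """Samples x genes relative-quantity matrix for geNorm screening."""
    wide = ct_table[ct_table["gene"].isin(candidate_refs)].pivot(
        index="sample_id", columns="gene", values="ct"
    )
    log2_e = np.log2(efficiency)
    return np.exp2((wide.min(axis=0) - wide) * log2_e)


def fold_change(
    relexpr: pd.DataFrame,
    gene: str,
    group_1: list[float],
    group_2: list[float],
    species: str | None = None,
) -> float:
    """Ratio of mean relative expression between two timepoint groups."""
    sub = relexpr[relexpr["gene"] == gene]
    if species is not None:
        sub = sub[sub["species"] == species]
    g1 = sub.loc[sub["timepoint_h"].isin(group_1), "rel_expr"].dropna()
    g2 = sub.loc[sub["timepoint_h"].isin(group_2), "rel_expr"].dropna()
    if g1.empty or g2.empty:
        raise ValueError("both timepoint groups must contain observations")
    return float(g1.mean() / g2.mean())
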