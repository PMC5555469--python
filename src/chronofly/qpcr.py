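"""Relative qPCR quantification, circadian phase, and splice-isoform analysis.

Implements the classic delta-Cq scheme: technical triplicates are averaged,
expression relative to a reference transcript is ``efficiency**-(Cq_gene -
Cq_ref)``, and each gene's series is normalized to the sample with the
highest expression so curves from several conditions share one relative
axis.  Peak phase comes from the argmax of the mean series or from a
single-harmonic cosinor fit; splicing efficiency is the spliced fraction
``spliced / (spliced + unspliced)`` of an isoform pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

CQ_COLUMNS = ["gene", "condition", "zt", "bio_rep", "tech_rep", "cq"]


@dataclass
class RelExpressionSeries:
    """Normalized relative expression of one gene, possibly across conditions.

    ``points`` has one row per (condition, zt) with columns
    ``condition, zt, mean_rel, sd_rel, n_bio``; ``replicates`` keeps the
    per-biological-replicate values (columns ``condition, zt, bio_rep,
    rel``) on the same normalized scale for downstream tests.
    """

    gene: str
    ref_gene: str
    points: pd.DataFrame
    replicates: pd.DataFrame
    normalized_jointly: bool = True

    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.points["condition"]))


@dataclass
class PhaseEstimate:
    gene: str
    condition_label: str
    peak_zt: float
    method: str
    cycling: bool = True
    amplitude: float | None = None
    fit_quality: float | None = None


def _validate_cq_table(cq: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CQ_COLUMNS if c not in cq.columns]
    if missing:
        raise ValueError(f"Cq table is missing columns: {missing}")
    if (cq["cq"] <= 0).any():
        raise ValueError("Cq values must be positive cycle numbers")
    return cq


def collapse_technical(cq: pd.DataFrame, max_spread: float = 0.5,
                       ref_gene: str | None = None) -> pd.DataFrame:
    """Average technical replicates into one Cq per biological sample.

    A sample whose technical max-min spread exceeds ``max_spread`` cycles is
    flagged (``qc_flag=True``) but kept: there is no exclusion rule to apply,
    and dropping wells silently would bias dispersion estimates.  When
    ``ref_gene`` is given, every (condition, zt, bio_rep) sample must carry
    reference rows; a missing reference raises naming the sample.
    """
    cq = _validate_cq_table(cq)
    grouped = cq.groupby(["gene", "condition", "zt", "bio_rep"], sort=True)["cq"]
    out = grouped.agg(cq="mean", n_tech="size",
                      spread=lambda v: v.max() - v.min()).reset_index()
    out["qc_flag"] = out["spread"] > max_spread
    if ref_gene is not None:
        samples = out[["condition", "zt", "bio_rep"]].drop_duplicates()
        have_ref = out.loc[out["gene"] == ref_gene, ["condition", "zt", "bio_rep"]]
        merged = samples.merge(have_ref, how="left", indicator=True,
                               on=["condition", "zt", "bio_rep"])
        lacking = merged[merged["_merge"] == "left_only"]
        if len(lacking):
            row = lacking.iloc[0]
            raise ValueError(
                f"no reference gene {ref_gene!r} rows for sample "
                f"(condition={row['condition']!r}, zt={row['zt']}, "
                f"bio_rep={row['bio_rep']})"
            )
    return out


def relative_expression(cq_collapsed: pd.DataFrame, gene: str, ref_gene: str,
                        efficiency: float = 2.0,
                        normalize_jointly: bool = True) -> RelExpressionSeries:
    """Delta-Cq relative expression, max-normalized.

    Per biological replicate, ``rel = efficiency**-(Cq_gene - Cq_ref)``.
    Means and SDs are taken over biological replicates at each
    (condition, zt).  The whole series is then divided by the maximum
    per-timepoint mean — across all conditions jointly by default, so
    several temperature curves share one axis with a single global maximum
    of 1 — or within each condition when ``normalize_jointly=False``.
    """
    if efficiency <= 1.0:
        raise ValueError(f"amplification efficiency must be > 1, got {efficiency}")
    sub = cq_collapsed[cq_collapsed["gene"] == gene]
    ref = cq_collapsed[cq_collapsed["gene"] == ref_gene]
    if sub.empty:
        raise ValueError(f"gene {gene!r} not present in the collapsed table")
    if ref.empty:
        raise ValueError(f"reference gene {ref_gene!r} not present")
    merged = sub.merge(ref, on=["condition", "zt", "bio_rep"],
                       suffixes=("", "_ref"), how="left")
    if merged["cq_ref"].isna().any():
        row = merged[merged["cq_ref"].isna()].iloc[0]
        raise ValueError(
            f"no reference gene {ref_gene!r} rows for sample "
            f"(condition={row['condition']!r}, zt={row['zt']}, "
            f"bio_rep={row['bio_rep']})"
        )
    merged["rel"] = efficiency ** -(merged["cq"] - merged["cq_ref"])

    pts = merged.groupby(["condition", "zt"], sort=True)["rel"].agg(
        mean_rel="mean",
        sd_rel=lambda v: v.std(ddof=1) if len(v) > 1 else 0.0,
        n_bio="size",
    ).reset_index()

    reps = merged[["condition", "zt", "bio_rep", "rel"]].copy()
    if normalize_jointly:
        scale = pts["mean_rel"].max()
        pts[["mean_rel", "sd_rel"]] /= scale
        reps["rel"] /= scale
    else:
        for cond, idx in pts.groupby("condition").groups.items():
            scale = pts.loc[idx, "mean_rel"].max()
            pts.loc[idx, ["mean_rel", "sd_rel"]] /= scale
            reps.loc[reps["condition"] == cond, "rel"] /= scale
    return RelExpressionSeries(
        gene=gene, ref_gene=ref_gene, points=pts, replicates=reps,
        normalized_jointly=normalize_jointly,
    )


def _single_condition(series: RelExpressionSeries,
                      condition: str | None) -> tuple[str, pd.DataFrame]:
    conds = series.conditions()
    if condition is None:
        if len(conds) != 1:
            raise ValueError(
                f"series covers conditions {conds}; specify which one to use"
            )
        condition = conds[0]
    sub = series.points[series.points["condition"] == condition]
    if sub.empty:
        raise ValueError(f"condition {condition!r} not in series")
    return condition, sub.sort_values("zt")


def peak_phase(series: RelExpressionSeries, method: str = "argmax",
               condition: str | None = None) -> PhaseEstimate:
    """Estimate the acrophase (ZT of maximal expression) of one condition.

    ``argmax`` takes the ZT of the maximal mean (ties broken to the
    earliest ZT); ``cosinor`` least-squares fits
    ``m + a*cos(2*pi*(t - phi)/24)`` with a >= 0 enforced by the phase
    convention and reports phi mod 24 plus the fit R^2.  A flat series is
    flagged non-cycling.
    """
    condition, sub = _single_condition(series, condition)
    t = sub["zt"].to_numpy(dtype=float)
    y = sub["mean_rel"].to_numpy(dtype=float)
    if len(t) < 4 or t.max() - t.min() < 24.0 - (t[1] - t[0]) - 1e-9:
        raise ValueError("need >= 4 timepoints spanning a full 24-h cycle")
    flat = np.ptp(y) < 1e-12
    if method == "argmax":
        peak = float(t[int(np.argmax(y))])  # argmax takes the earliest maximum
        return PhaseEstimate(series.gene, condition, peak % 24.0, "argmax",
                             cycling=not flat)
    if method == "cosinor":
        w = 2.0 * np.pi / 24.0
        X = np.column_stack([np.ones_like(t), np.cos(w * t), np.sin(w * t)])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        amp = float(np.hypot(beta[1], beta[2]))
        phi = float(np.arctan2(beta[2], beta[1]) / w) % 24.0
        resid = y - X @ beta
        tss = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid ** 2)) / tss if tss > 0 else 0.0
        return PhaseEstimate(series.gene, condition, phi, "cosinor",
                             cycling=not flat, amplitude=amp, fit_quality=r2)
    raise ValueError(f"unknown phase method {method!r}")


def phase_shift(a: PhaseEstimate, b: PhaseEstimate) -> float:
    """Minimal signed circular phase difference b - a, in (-12, +12] hours.

    Negative values mean b peaks earlier (a phase advance of b relative
    to a); the comparison requires estimates of the same gene and method.
    """
    if a.gene != b.gene:
        raise ValueError(f"cannot compare phases of {a.gene!r} and {b.gene!r}")
    if a.method != b.method:
        raise ValueError(
            f"phase methods differ ({a.method!r} vs {b.method!r})"
        )
    d = (b.peak_zt - a.peak_zt) % 24.0
    if d > 12.0:
        d -= 24.0
    return d


def splicing_efficiency(assays: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-condition splicing efficiency and pairwise condition contrasts.

    ``assays`` must have columns ``condition, replicate, spliced_level,
    unspliced_level`` with positive levels.  The per-replicate efficiency is
    ``spliced / (spliced + unspliced)``.  Returns ``(summary, pairwise)``:
    the summary holds mean, SD and n per condition; the pairwise frame
    holds the mean difference in percentage points and a Welch t-test on
    the log isoform ratio ``log(spliced/unspliced)`` (the efficiency's
    logit, where variances are comparable), BH-adjusted across pairs.
    """
    required = {"condition", "replicate", "spliced_level", "unspliced_level"}
    if not required.issubset(assays.columns):
        raise ValueError(f"assay table needs columns {sorted(required)}")
    total = assays["spliced_level"] + assays["unspliced_level"]
    if (assays["spliced_level"] <= 0).any() or (assays["unspliced_level"] <= 0).any():
        raise ValueError("isoform levels must be positive to form an efficiency")
    eff = assays.assign(
        efficiency=assays["spliced_level"] / total,
        log_ratio=np.log(assays["spliced_level"] / assays["unspliced_level"]),
    )
    summary = eff.groupby("condition", sort=True)["efficiency"].agg(
        mean_efficiency="mean",
        sd_efficiency=lambda v: v.std(ddof=1) if len(v) > 1 else 0.0,
        n="size",
    ).reset_index()

    rows = []
    for c1, c2 in combinations(summary["condition"], 2):
        g1 = eff.loc[eff["condition"] == c1]
        g2 = eff.loc[eff["condition"] == c2]
        diff_pp = 100.0 * (g2["efficiency"].mean() - g1["efficiency"].mean())
        if len(g1) > 1 and len(g2) > 1:
            p = stats.ttest_ind(g2["log_ratio"], g1["log_ratio"],
                                equal_var=False).pvalue
        else:
            p = np.nan
        rows.append({"condition_a": c1, "condition_b": c2,
                     "difference_pp": diff_pp, "p_value": p})
    pairwise = pd.DataFrame(rows)
    if len(pairwise) and pairwise["p_value"].notna().any():
        mask = pairwise["p_value"].notna()
        pairwise.loc[mask, "p_adj"] = multipletests(
            pairwise.loc[mask, "p_value"], method="fdr_bh")[1]
    else:
        pairwise["p_adj"] = np.nan
    return summary, pairwise


def cycling_test(series: RelExpressionSeries,
                 condition: str | None = None) -> tuple[float, bool]:
    """One-way F test for a timepoint effect on log relative expression.

    Uses the per-biological-replicate values of one condition; returns
    ``(p_value, defined)`` where ``defined=False`` marks a degenerate
    (zero-variance) series whose F statistic does not exist — reported as
    non-cycling.  Use :func:`cycling_tests` to BH-correct across genes.
    """
    conds = list(dict.fromkeys(series.replicates["condition"]))
    if condition is None:
        if len(conds) != 1:
            raise ValueError(f"series covers conditions {conds}; pick one")
        condition = conds[0]
    sub = series.replicates[series.replicates["condition"] == condition]
    groups = [np.log(g["rel"].to_numpy()) for _, g in sub.groupby("zt", sort=True)]
    if len(groups) < 2:
        raise ValueError("cycling test needs at least two timepoints")
    if any(len(g) < 2 for g in groups):
        raise ValueError("cycling test needs >= 2 biological replicates per timepoint")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) < 1e-12:
        return float("nan"), False
    f, p = stats.f_oneway(*groups)
    if not np.isfinite(p):
        return float("nan"), False
    return float(p), True


def cycling_tests(series_list: list[RelExpressionSeries],
                  condition: str | None = None,
                  alpha: float = 0.05) -> pd.DataFrame:
    """Apply :func:`cycling_test` per gene with BH correction across genes."""
    rows = []
    for s in series_list:
        p, defined = cycling_test(s, condition=condition)
        rows.append({"gene": s.gene, "p_value": p, "defined": defined})
    df = pd.DataFrame(rows)
    mask = df["defined"] & df["p_value"].notna()
    df["p_adj"] = np.nan
    if mask.any():
        df.loc[mask, "p_adj"] = multipletests(df.loc[mask, "p_value"],
                                              method="fdr_bh")[1]
    df["cycling"] = df["p_adj"] < alpha
    df.loc[~df["defined"], "cycling"] = False
    return df
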