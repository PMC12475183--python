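"""Group-level CKC contrasts: lateralization, frequency specificity,
method-by-resolution SNR comparison, and cross-condition correlations.

This module only assembles exact inputs for established statistical routines
(scipy.stats Shapiro-Wilk / Wilcoxon signed-rank / paired t / Spearman,
statsmodels repeated-measures ANOVA); it implements no test internals.  All
operations are pure functions of the tidy per-condition subject table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CKCMetrics, CoherenceSpectrum
from .montage import Montage

#: Coherence is tabulated at the target frequencies, the 3 Hz baseline and
#: the +/-0.5 Hz neighbors used in the frequency-specificity contrasts.
TABLE_FREQS_HZ = (1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 4.5)

NORMALITY_ALPHA = 0.05
RIGHT_HANDED_LQ = 40.0  # laterality quotient above this => right-handed


def _coh_col(f: float) -> str:
    return f"coh_{f:g}hz"


def dominant_hand(laterality_quotient: float) -> str:
    """Dominant hand from the Edinburgh laterality quotient.

    Positive quotients map to right dominance, non-positive to left; this
    reproduces the ambidextrous special case (quotient slightly below zero =>
    left dominant).  The conventional right-handed *classification* threshold
    (quotient > 40) is exported as ``RIGHT_HANDED_LQ``.
    """
    return "right" if laterality_quotient > 0 else "left"


def metrics_row(
    metrics: CKCMetrics,
    spectrum: CoherenceSpectrum,
    montage: Montage,
    subject: str,
    laterality_quotient: float,
) -> dict:
    """One tidy SubjectTable row from a spectrum and its metrics.

    The tabulated per-frequency coherence is the maximum across the analysis
    subset at that bin (the same extraction used for the spectra figures).
    """
    idx = [spectrum.channels.index(l) for l in montage.subsets["analysis"]]
    row = {
        "subject": subject,
        "hand": metrics.hand,
        "dominant_hand": dominant_hand(laterality_quotient),
        "laterality_quotient": laterality_quotient,
        "block": metrics.block,
        "accel_method": metrics.accel_method,
        "averaging": metrics.averaging,
        "resolution_hz": metrics.resolution_hz,
        "f0_hz": metrics.f0_hz,
        "f1_hz": metrics.f1_hz,
        "f0_peak": metrics.peak_f0,
        "f1_peak": metrics.peak_f1,
        "f0_peak_channel": metrics.peak_channel_f0,
        "f1_peak_channel": metrics.peak_channel_f1,
        "snr_f0_db": metrics.snr_f0_db,
        "snr_f1_db": metrics.snr_f1_db,
        "mean_left_f0": metrics.mean_left_f0,
        "mean_right_f0": metrics.mean_right_f0,
        "mean_left_f1": metrics.mean_left_f1,
        "mean_right_f1": metrics.mean_right_f1,
        "contra_f0": metrics.contra_f0,
        "ipsi_f0": metrics.ipsi_f0,
        "contra_f1": metrics.contra_f1,
        "ipsi_f1": metrics.ipsi_f1,
    }
    for f in TABLE_FREQS_HZ:
        row[_coh_col(f)] = float(spectrum.at(f)[idx].max())
    return row


def build_subject_table(rows) -> pd.DataFrame:
    """Validated tidy table: one row per subject x hand x block x method cell."""
    table = pd.DataFrame(list(rows))
    keys = ["subject", "hand", "block", "accel_method", "averaging", "resolution_hz"]
    present = [k for k in keys if k in table.columns]
    if table.duplicated(subset=present).any():
        raise ValueError("duplicate subject/hand/block/method rows")
    coh_cols = [c for c in table.columns if c.startswith("coh_")]
    if coh_cols:
        vals = table[coh_cols].to_numpy()
        if np.any(vals < 0) or np.any(vals > 1):
            raise ValueError("coherence columns must lie in [0, 1]")
    return table


def _freq_key(table: pd.DataFrame, freq_hz: float) -> str:
    if np.isclose(freq_hz, table["f0_hz"].iloc[0]):
        return "f0"
    if np.isclose(freq_hz, table["f1_hz"].iloc[0]):
        return "f1"
    raise ValueError(f"{freq_hz} Hz is neither the fundamental nor the harmonic")


def _signed_rank(diffs: np.ndarray) -> tuple[float, float]:
    if np.allclose(diffs, 0):
        return 0.0, 1.0
    res = stats.wilcoxon(diffs)
    return float(res.statistic), float(res.pvalue)


def lateralization_contrast(table: pd.DataFrame, freq_hz: float) -> tuple[pd.DataFrame, dict]:
    """Per-subject contralateral-vs-ipsilateral coherence pairs and tests.

    Contra/ipsi are recomputed from the left/right set means and the hand
    label (so the contrast is antisymmetric under swapping hand labels).
    Blocks are averaged within subject x hand.  Returns ``(pairs, tests)``
    with one Shapiro-Wilk screen + Wilcoxon signed-rank summary per hand.
    """
    fkey = _freq_key(table, freq_hz)
    hands = set(table["hand"])
    if hands != {"left", "right"}:
        raise ValueError("both hand conditions must be present")
    if table["subject"].nunique() < 2:
        raise ValueError("paired contrast undefined for a single subject")
    g = (
        table.groupby(["subject", "hand"], as_index=False)[
            [f"mean_left_{fkey}", f"mean_right_{fkey}"]
        ].mean()
    )
    contra = np.where(
        g["hand"] == "left", g[f"mean_right_{fkey}"], g[f"mean_left_{fkey}"]
    )
    ipsi = np.where(
        g["hand"] == "left", g[f"mean_left_{fkey}"], g[f"mean_right_{fkey}"]
    )
    pairs = g[["subject", "hand"]].assign(contra=contra, ipsi=ipsi)
    pairs["diff"] = pairs["contra"] - pairs["ipsi"]
    tests = {}
    for hand in ("left", "right"):
        d = pairs.loc[pairs["hand"] == hand, "diff"].to_numpy()
        w, wp = stats.shapiro(d) if d.size >= 3 else (np.nan, np.nan)
        v, vp = _signed_rank(d)
        tests[hand] = {
            "n": int(d.size),
            "median_diff": float(np.median(d)),
            "shapiro_w": float(w),
            "shapiro_p": float(wp),
            "wilcoxon_v": v,
            "wilcoxon_p": vp,
            "direction": "contra>ipsi" if np.median(d) > 0 else "contra<=ipsi",
        }
    return pairs, tests


def frequency_specificity(
    table: pd.DataFrame,
    f_target: float,
    f_neighbors: tuple[float, ...],
) -> tuple[pd.DataFrame, dict]:
    """Per-subject target-vs-neighbor coherence differences and paired tests.

    For each neighbor the Shapiro-Wilk screen (alpha = 0.05) picks the primary
    test (paired t if normal, Wilcoxon signed-rank otherwise); both statistics
    are reported.  Rows are averaged within subject before pairing.
    """
    tcol = _coh_col(f_target)
    if tcol not in table.columns:
        raise ValueError(f"coherence at {f_target} Hz not tabulated")
    diffs_frames = []
    tests = {}
    for f in f_neighbors:
        ncol = _coh_col(f)
        if ncol not in table.columns:
            raise ValueError(f"neighbor bin {f} Hz not on the tabulated grid")
        g = table.groupby("subject", as_index=False)[[tcol, ncol]].mean()
        d = (g[tcol] - g[ncol]).to_numpy()
        diffs_frames.append(
            pd.DataFrame(
                {"subject": g["subject"], "neighbor_hz": f, "diff": d}
            )
        )
        if np.allclose(d, d[0]):
            sw, sp = np.nan, np.nan
        else:
            sw, sp = stats.shapiro(d)
        t_stat, t_p = stats.ttest_rel(g[tcol], g[ncol])
        v, vp = _signed_rank(d)
        normal = bool(sp > NORMALITY_ALPHA) if np.isfinite(sp) else False
        tests[f] = {
            "n": int(d.size),
            "mean_diff": float(d.mean()),
            "shapiro_w": float(sw),
            "shapiro_p": float(sp),
            "chosen_test": "paired_t" if normal else "wilcoxon",
            "t_stat": float(t_stat),
            "t_p": float(t_p),
            "wilcoxon_v": v,
            "wilcoxon_p": vp,
        }
    return pd.concat(diffs_frames, ignore_index=True), tests


def snr_method_table(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cell and marginal summaries of dB SNR over the 16-cell method grid.

    Cells are accel_method x averaging x resolution (2 x 2 x 4); each subject
    must cover the full grid.  Returns ``(cells, marginals)`` with mean and SD
    of SNR at F0 and F1.  On balanced input the factor marginal means equal
    the means of the corresponding cell means (no silent reweighting).
    """
    factors = ["accel_method", "averaging", "resolution_hz"]
    per_subj = table.groupby(["subject"] + factors, as_index=False)[
        ["snr_f0_db", "snr_f1_db"]
    ].mean()
    counts = per_subj.groupby("subject").size()
    if (counts != 16).any():
        raise ValueError("each subject must cover the full 16-cell grid")
    cells = per_subj.groupby(factors, as_index=False).agg(
        snr_f0_mean=("snr_f0_db", "mean"),
        snr_f0_sd=("snr_f0_db", "std"),
        snr_f1_mean=("snr_f1_db", "mean"),
        snr_f1_sd=("snr_f1_db", "std"),
        n=("snr_f0_db", "size"),
    )
    marg_frames = []
    for factor in factors:
        m = per_subj.groupby(factor, as_index=False)[["snr_f0_db", "snr_f1_db"]].mean()
        m.insert(0, "factor", factor)
        m = m.rename(columns={factor: "level"})
        marg_frames.append(m)
    marginals = pd.concat(marg_frames, ignore_index=True)
    return cells, marginals


def snr_anova(table: pd.DataFrame, freq: str = "f0") -> pd.DataFrame:
    """Three-way repeated-measures ANOVA of dB SNR, delegated to statsmodels."""
    from statsmodels.stats.anova import AnovaRM

    col = f"snr_{freq}_db"
    long = table.groupby(
        ["subject", "accel_method", "averaging", "resolution_hz"], as_index=False
    )[col].mean()
    res = AnovaRM(
        long,
        depvar=col,
        subject="subject",
        within=["accel_method", "averaging", "resolution_hz"],
    ).fit()
    return res.anova_table


def _peak_by(table: pd.DataFrame, key: str, fkey: str, pooling: str) -> pd.DataFrame:
    col = f"{fkey}_peak"
    agg = {"max": "max", "mean": "mean"}[pooling]
    return table.groupby(["subject", key], as_index=False)[col].agg(agg)


def condition_correlations(
    table: pd.DataFrame, pooling: str = "max", min_subjects: int = 5
) -> pd.DataFrame:
    """Spearman correlations of peak CKC across conditions.

    Correlates left vs right hand (and dominant vs non-dominant) peak
    coherence at F0 and F1, the F0-vs-F1 relation within each hand, and peak
    coherence against the absolute laterality quotient.  ``pooling`` collapses
    blocks within subject x hand ("max" keeps the per-subject maximum).
    P-values are uncorrected for multiple comparisons.
    """
    n_subj = table["subject"].nunique()
    if n_subj < min_subjects:
        raise ValueError(f"refusing correlations with n={n_subj} < {min_subjects}")
    lq = table.groupby("subject")["laterality_quotient"].first()
    dom = table.groupby("subject")["dominant_hand"].first()

    def pivot(key: str, fkey: str) -> pd.DataFrame:
        return _peak_by(table, key, fkey, pooling).pivot(
            index="subject", columns=key, values=f"{fkey}_peak"
        )

    hand_f0 = pivot("hand", "f0")
    hand_f1 = pivot("hand", "f1")
    table = table.assign(
        dom_cond=np.where(
            table["hand"] == table["dominant_hand"], "dominant", "nondominant"
        )
    )
    dom_f0 = pivot("dom_cond", "f0")
    dom_f1 = pivot("dom_cond", "f1")

    rows = []

    def corr(name: str, a: pd.Series, b: pd.Series):
        joined = pd.concat([a, b], axis=1, join="inner").dropna()
        rho, p = stats.spearmanr(joined.iloc[:, 0], joined.iloc[:, 1])
        rows.append(
            {
                "comparison": name,
                "rho": float(rho),
                "p_uncorrected": float(p),
                "n": len(joined),
            }
        )

    corr("right2_vs_left2", hand_f0["right"], hand_f0["left"])
    corr("right4_vs_left4", hand_f1["right"], hand_f1["left"])
    corr("right2_vs_right4", hand_f0["right"], hand_f1["right"])
    corr("left2_vs_left4", hand_f0["left"], hand_f1["left"])
    corr("dom2_vs_nondom2", dom_f0["dominant"], dom_f0["nondominant"])
    corr("dom4_vs_nondom4", dom_f1["dominant"], dom_f1["nondominant"])
    abs_lq = lq.abs()
    corr("abslq_vs_dom2", abs_lq, dom_f0["dominant"])
    corr("abslq_vs_dom4", abs_lq, dom_f1["dominant"])
    corr("abslq_vs_nondom2", abs_lq, dom_f0["nondominant"])
    corr("abslq_vs_nondom4", abs_lq, dom_f1["nondominant"])
    out = pd.DataFrame(rows)
    out.attrs["p_correction"] = "none (uncorrected)"
    return out


def holm_correct(pvalues: np.ndarray) -> np.ndarray:
    """Optional Holm step-down adjustment for the correlation tables."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(pvalues, method="holm")[1]
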