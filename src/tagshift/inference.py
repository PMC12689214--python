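"""Statistics for SSVEP modulation time courses and behavior.

Implements the full inferential toolkit of the analysis:

* running paired/one-sample t-tests with cluster-sum permutation
  correction (within-subject sign flips, max-cluster null, 5000
  iterations by default),
* Jeffreys-Zellner-Siow (JZS) Bayes factors for paired contrasts with
  a Cauchy prior of scale r = 0.71, pointwise over time, with a
  null-acceptance mask at BF10 < 0.33,
* jackknife onset-latency estimation (leave-one-subject-out grand
  averages, onset at 85 % of the base-to-peak range, Smulders
  back-transform to individual onsets),
* window-averaged condition contrasts (750-1250 ms) with paired t,
  Cohen's d and BF10,
* repeated-measures ANOVA with Greenhouse-Geisser correction and Holm
  adjustment for post-hoc tests, and
* the a priori sample-size calculation from noncentral-t power.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import integrate, ndimage, stats

__all__ = [
    "ClusterTestResult", "BFTimecourse", "OnsetEstimates",
    "running_cluster_test", "jzs_bf_paired", "jzs_bf_from_t", "running_bf",
    "jackknife_onsets", "compare_onsets", "window_contrasts",
    "rm_anova", "holm_adjust", "apriori_n", "power_paired_t",
]

_ROW_STRUCTURE = np.array([[0, 0, 0], [1, 1, 1], [0, 0, 0]])


# ----------------------------------------------------------------------
# cluster-permutation running t-tests
# ----------------------------------------------------------------------
@dataclass
class ClusterTestResult:
    """Clusters of contiguous significant time points with permutation p."""

    clusters: pd.DataFrame  # start_ms, end_ms, sum_t, p_value
    t_values: np.ndarray
    times: np.ndarray
    tail: str
    alpha: float
    n_perm: int
    seed: int

    def significant_mask(self, alpha: float | None = None) -> np.ndarray:
        """Boolean mask of time points inside significant clusters."""
        alpha = self.alpha if alpha is None else alpha
        mask = np.zeros(len(self.times), dtype=bool)
        for _, c in self.clusters.iterrows():
            if c["p_value"] < alpha:
                mask[int(c["start_idx"]): int(c["end_idx"]) + 1] = True
        return mask

    @property
    def significant_clusters(self) -> pd.DataFrame:
        return self.clusters[self.clusters["p_value"] < self.alpha]


def _paired_t(diff: np.ndarray) -> np.ndarray:
    """One-sample t over axis 0; zero-variance points yield t = 0."""
    n = diff.shape[0]
    mean = diff.mean(axis=0)
    sd = diff.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    bad = ~np.isfinite(t)
    if bad.any():
        t = np.where(bad, 0.0, t)
    return t


def _max_cluster_stats(t_mat: np.ndarray, crit: float, tail: str) -> np.ndarray:
    """Max cluster-sum statistic per row of a (rows, time) t matrix."""
    if tail == "greater":
        mask = t_mat > crit
        vals = t_mat
    elif tail == "less":
        mask = t_mat < -crit
        vals = -t_mat
    else:
        mask = np.abs(t_mat) > crit
        vals = np.abs(t_mat)
    labels, n_lab = ndimage.label(mask, structure=_ROW_STRUCTURE)
    out = np.zeros(t_mat.shape[0])
    if n_lab:
        sums = ndimage.sum_labels(vals, labels, index=np.arange(1, n_lab + 1))
        rows = ndimage.minimum(
            np.repeat(np.arange(t_mat.shape[0])[:, None], t_mat.shape[1], 1),
            labels, index=np.arange(1, n_lab + 1),
        ).astype(int)
        np.maximum.at(out, rows, sums)
    return out


def running_cluster_test(
    x: np.ndarray,
    y: np.ndarray | None = None,
    times: np.ndarray | None = None,
    tail: str = "greater",
    alpha: float = 0.05,
    n_perm: int = 5000,
    seed: int = 0,
) -> ClusterTestResult:
    """Cluster-corrected running t-test on subject-by-time data.

    ``x`` (and optionally ``y``, aligned) are (subjects, time) arrays;
    the test is paired (one-sample on the difference, or against zero
    when ``y`` is None).  Pointwise t-values exceeding the critical
    value at ``alpha`` form contiguous clusters whose summed t is
    compared against the permutation distribution of the maximum
    cluster sum under within-subject sign flips of the difference
    (equivalent to shuffling condition labels per subject).  Time
    points with zero variance are treated as non-significant with a
    warning.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    diff = x - np.asarray(y, dtype=float) if y is not None else x
    n, n_time = diff.shape
    if n < 5:
        raise ValueError("cluster test requires at least 5 subjects")
    if tail not in ("greater", "less", "two-sided"):
        raise ValueError(f"unknown tail {tail!r}")
    if times is None:
        times = np.arange(n_time, dtype=float) / 1000.0
    df_ = n - 1
    crit = stats.t.ppf(1 - alpha / (2 if tail == "two-sided" else 1), df_)

    sd = diff.std(axis=0, ddof=1)
    if np.any(sd == 0):
        warnings.warn("zero variance at some time points; treated as non-significant")
    t_obs = _paired_t(diff)

    # observed clusters
    if tail == "greater":
        sig = t_obs > crit
    elif tail == "less":
        sig = t_obs < -crit
    else:
        sig = np.abs(t_obs) > crit
    labels, n_lab = ndimage.label(sig)
    records = []
    for lab in range(1, n_lab + 1):
        idx = np.where(labels == lab)[0]
        s = t_obs[idx].sum()
        records.append(
            {"start_idx": idx[0], "end_idx": idx[-1],
             "start_ms": times[idx[0]] * 1000.0, "end_ms": times[idx[-1]] * 1000.0,
             "sum_t": s}
        )

    # permutation null: within-subject sign flips, vectorized
    rng = np.random.default_rng(seed)
    sq_sum = (diff**2).sum(axis=0)  # invariant under sign flips
    null_max = np.empty(n_perm)
    block = 500
    for start in range(0, n_perm, block):
        b = min(block, n_perm - start)
        flips = rng.choice([-1.0, 1.0], size=(b, n))
        means = flips @ diff / n
        var = (sq_sum / n - means**2) * (n / df_)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_perm = means / np.sqrt(var / n)
        t_perm[~np.isfinite(t_perm)] = 0.0
        null_max[start: start + b] = _max_cluster_stats(t_perm, crit, tail)

    for rec in records:
        obs = rec["sum_t"] if tail != "less" else -rec["sum_t"]
        if tail == "two-sided":
            obs = abs(obs)
        rec["p_value"] = (1.0 + np.sum(null_max >= obs)) / (n_perm + 1.0)
    cols = ["start_idx", "end_idx", "start_ms", "end_ms", "sum_t", "p_value"]
    clusters = pd.DataFrame(records, columns=cols)
    return ClusterTestResult(
        clusters=clusters, t_values=t_obs, times=np.asarray(times),
        tail=tail, alpha=alpha, n_perm=n_perm, seed=seed,
    )


# ----------------------------------------------------------------------
# JZS Bayes factors
# ----------------------------------------------------------------------
def jzs_bf_from_t(t: float, n: int, r: float = 0.71) -> float:
    """JZS Bayes factor BF10 from a one-sample/paired t statistic.

    The marginal likelihood under H1 integrates the noncentral-t
    likelihood over the Cauchy(0, r) prior on the standardized effect
    size; H0 is the point null.  Evaluated by adaptive quadrature.
    """
    nu = n - 1
    if nu < 1:
        raise ValueError("need at least 2 paired observations")
    sqrt_n = np.sqrt(n)

    def integrand(delta: float) -> float:
        return stats.nct.pdf(t, nu, delta * sqrt_n) * stats.cauchy.pdf(delta, 0.0, r)

    num, _ = integrate.quad(integrand, -np.inf, np.inf, limit=200)
    den = stats.t.pdf(t, nu)
    return float(num / den)


def jzs_bf_paired(
    x: np.ndarray, y: np.ndarray | None = None, r: float = 0.71
) -> float:
    """Paired Bayesian t-test (JZS, Cauchy prior scale ``r``)."""
    x = np.asarray(x, dtype=float)
    diff = x - np.asarray(y, dtype=float) if y is not None else x
    n = len(diff)
    if n < 2:
        raise ValueError("need at least 2 paired observations")
    sd = diff.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance differences: Bayes factor undefined")
    t = diff.mean() / (sd / np.sqrt(n))
    return jzs_bf_from_t(t, n, r)


@dataclass
class BFTimecourse:
    """Pointwise BF10 for a paired contrast over time."""

    times: np.ndarray
    bf10: np.ndarray
    r: float = 0.71
    null_threshold: float = 0.33

    @property
    def null_mask(self) -> np.ndarray:
        """Time points where the data favor the null (BF10 < threshold)."""
        return self.bf10 < self.null_threshold


def running_bf(
    x: np.ndarray,
    y: np.ndarray | None = None,
    times: np.ndarray | None = None,
    r: float = 0.71,
    null_threshold: float = 0.33,
) -> BFTimecourse:
    """JZS Bayes factor at every time point of a paired contrast."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    diff = x - np.asarray(y, dtype=float) if y is not None else x
    n, n_time = diff.shape
    if times is None:
        times = np.arange(n_time, dtype=float) / 1000.0
    bf = np.empty(n_time)
    for i in range(n_time):
        bf[i] = jzs_bf_paired(diff[:, i], r=r)
    return BFTimecourse(times=np.asarray(times), bf10=bf, r=r,
                        null_threshold=null_threshold)


# ----------------------------------------------------------------------
# jackknife onset latencies
# ----------------------------------------------------------------------
@dataclass
class OnsetEstimates:
    """Leave-one-out and back-transformed individual onset latencies."""

    subsample_onsets_ms: np.ndarray
    individual_onsets_ms: np.ndarray
    grand_onset_ms: float
    criterion: float
    base: float
    peak: float

    @property
    def n(self) -> int:
        return len(self.subsample_onsets_ms)


def _onset_of_trace(
    trace: np.ndarray,
    times_ms: np.ndarray,
    criterion: float,
    base: float,
    search: np.ndarray,
) -> tuple[float, float]:
    """First time the trace reaches base + criterion*(peak-base); NaN if never."""
    seg = trace[search]
    t_seg = times_ms[search]
    peak = seg.max()
    thresh = base + criterion * (peak - base)
    above = seg >= thresh
    if not above.any():
        return np.nan, peak
    i = int(np.argmax(above))
    if i == 0:
        return float(t_seg[0]), peak
    # linear interpolation between the straddling samples
    y0, y1 = seg[i - 1], seg[i]
    t0, t1 = t_seg[i - 1], t_seg[i]
    frac = (thresh - y0) / (y1 - y0) if y1 != y0 else 0.0
    return float(t0 + frac * (t1 - t0)), peak


def jackknife_onsets(
    x: np.ndarray,
    times: np.ndarray,
    criterion: float = 0.85,
    search_window: tuple[float, float] = (0.0, 1.5),
    baseline_window: tuple[float, float] | None = None,
    max_missing: float = 0.2,
) -> OnsetEstimates:
    """Jackknife onset latencies of a subjects-by-time modulation array.

    For each leave-one-subject-out subsample, the onset is the first
    time (linearly interpolated) at which the subsample mean reaches
    ``criterion`` of its base-to-peak range inside ``search_window``
    (seconds).  The base is the mean over ``baseline_window`` or 0 for
    baseline-corrected traces.  Individual onsets follow the Smulders
    back-transform ``o_i = n*grand - (n-1)*o_(-i)``.  Subsamples that
    never reach the criterion yield missing onsets; more than
    ``max_missing`` of them aborts.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n = x.shape[0]
    times = np.asarray(times, dtype=float)
    times_ms = times * 1000.0
    search = (times >= search_window[0] - 1e-9) & (times <= search_window[1] + 1e-9)

    def base_of(trace: np.ndarray) -> float:
        if baseline_window is None:
            return 0.0
        lo, hi = baseline_window
        m = (times >= lo - 1e-9) & (times <= hi + 1e-9)
        return float(trace[m].mean())

    grand_trace = x.mean(axis=0)
    grand_onset, peak = _onset_of_trace(
        grand_trace, times_ms, criterion, base_of(grand_trace), search
    )
    if np.isnan(grand_onset):
        raise ValueError("grand-average trace never reaches the onset criterion")

    sub = np.empty(n)
    for i in range(n):
        trace = np.delete(x, i, axis=0).mean(axis=0)
        sub[i], _ = _onset_of_trace(trace, times_ms, criterion, base_of(trace), search)
    n_missing = int(np.isnan(sub).sum())
    if n_missing > max_missing * n:
        raise ValueError(
            f"{n_missing}/{n} jackknife subsamples never reach the onset criterion"
        )
    if n_missing:
        warnings.warn(f"{n_missing} jackknife subsamples without onset (excluded)")
    indiv = n * grand_onset - (n - 1) * sub
    return OnsetEstimates(
        subsample_onsets_ms=sub, individual_onsets_ms=indiv,
        grand_onset_ms=grand_onset, criterion=criterion,
        base=base_of(grand_trace), peak=float(peak),
    )


def compare_onsets(a: OnsetEstimates, b: OnsetEstimates) -> dict:
    """Paired two-tailed t-test on back-transformed individual onsets."""
    xa, xb = a.individual_onsets_ms, b.individual_onsets_ms
    ok = ~(np.isnan(xa) | np.isnan(xb))
    res = stats.ttest_rel(xa[ok], xb[ok])
    return {
        "t": float(res.statistic), "df": int(ok.sum() - 1),
        "p_value": float(res.pvalue),
        "mean_diff_ms": float(np.mean(xa[ok] - xb[ok])),
    }


# ----------------------------------------------------------------------
# window-averaged contrasts
# ----------------------------------------------------------------------
DEFAULT_CONTRASTS = (
    ("cued_vs_cued_match", ("cued",), ("cued_match",)),
    ("selectivity_diff_vs_same", ("cued", "-uncued"), ("cued_match", "-uncued_non_match")),
    ("uncued_match_vs_uncued", ("uncued_match",), ("uncued",)),
)


def _combine(traces: Mapping[str, np.ndarray], terms: Sequence[str]) -> np.ndarray:
    out = 0.0
    for term in terms:
        if term.startswith("-"):
            out = out - traces[term[1:]]
        else:
            out = out + traces[term]
    return out


def window_contrasts(
    traces: Mapping[str, np.ndarray],
    times: np.ndarray,
    window: tuple[float, float] = (0.75, 1.25),
    contrasts: Sequence[tuple] = DEFAULT_CONTRASTS,
    r: float = 0.71,
) -> pd.DataFrame:
    """Paired contrasts of window-averaged modulation (750-1250 ms).

    ``traces`` maps condition names to (subjects, time) arrays.  Each
    contrast is (name, terms_a, terms_b) where terms are condition
    names, optionally prefixed with '-' for differences (e.g. spatial
    selectivity = cued - uncued).  Reports two-tailed paired t, the
    difference-score Cohen's d, and the JZS BF10.
    """
    times = np.asarray(times, dtype=float)
    lo, hi = window
    if lo < times[0] or hi > times[-1]:
        raise ValueError("contrast window not inside the analysis window")
    m = (times >= lo - 1e-9) & (times <= hi + 1e-9)
    rows = []
    for name, terms_a, terms_b in contrasts:
        a = _combine(traces, terms_a)[:, m].mean(axis=1)
        b = _combine(traces, terms_b)[:, m].mean(axis=1)
        d = a - b
        n = len(d)
        sd = d.std(ddof=1)
        if sd == 0:
            t = 0.0
            p = 1.0
            cd = 0.0
        else:
            res = stats.ttest_rel(a, b)
            t, p = float(res.statistic), float(res.pvalue)
            cd = float(d.mean() / sd)
        bf = jzs_bf_from_t(t, n, r) if sd > 0 else np.nan
        rows.append({"contrast": name, "mean_diff": float(d.mean()), "t": t,
                     "df": n - 1, "p_value": p, "cohen_d": cd, "bf10": bf})
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# repeated-measures ANOVA, Holm, power
# ----------------------------------------------------------------------
def rm_anova(
    data: pd.DataFrame | np.ndarray,
    dv: str = "value",
    within: str | Sequence[str] = "level",
    subject: str = "subject",
) -> pd.DataFrame:
    """Univariate repeated-measures ANOVA with Greenhouse-Geisser output.

    ``data`` is either a long DataFrame or a (subjects, levels) array
    for the one-way case.  Requires a complete balanced design.
    Returns the pingouin table with GG-corrected p-values and epsilon;
    a factor with zero effect variance reports F = 0.
    """
    import pingouin as pg

    if isinstance(data, np.ndarray):
        n_sub, n_lev = data.shape
        data = pd.DataFrame({
            subject: np.repeat(np.arange(n_sub), n_lev),
            within: np.tile([f"l{i}" for i in range(n_lev)], n_sub),
            dv: data.ravel(),
        })
    within_list = [within] if isinstance(within, str) else list(within)
    counts = data.groupby([subject, *within_list], observed=True)[dv].count()
    n_cells = data[subject].nunique() * int(
        np.prod([data[w].nunique() for w in within_list])
    )
    if counts.empty or len(counts) != n_cells or counts.nunique() != 1:
        raise ValueError("rm_anova requires a complete balanced design")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = pg.rm_anova(
            data=data, dv=dv,
            within=within_list if len(within_list) > 1 else within_list[0],
            subject=subject, correction=True, detailed=True, effsize="ng2",
        )
    res = res[res["Source"] != "Error"].reset_index(drop=True)
    ss = res["SS"].to_numpy(dtype=float)
    y = data[dv].to_numpy(dtype=float)
    ss_total = float(((y - y.mean()) ** 2).sum())
    degenerate = ss <= 1e-12 * max(ss_total, 1.0)
    res.loc[degenerate, "F"] = 0.0
    res.loc[degenerate, "p_unc"] = 1.0
    if "p_GG_corr" in res:
        res.loc[degenerate, "p_GG_corr"] = 1.0
    return res


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Step-down Holm adjustment (monotone, capped at 1)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def power_paired_t(n: int, d: float, alpha: float = 0.05, tails: int = 2) -> float:
    """Power of a one-sample/paired t-test via the noncentral t."""
    df_ = n - 1
    if df_ < 1:
        return 0.0
    nc = d * np.sqrt(n)
    if tails == 2:
        crit = stats.t.ppf(1 - alpha / 2, df_)
        return float(1 - stats.nct.cdf(crit, df_, nc) + stats.nct.cdf(-crit, df_, nc))
    crit = stats.t.ppf(1 - alpha, df_)
    return float(1 - stats.nct.cdf(crit, df_, nc))


def apriori_n(
    d: float, power: float = 0.9, alpha: float = 0.05, tails: int = 2,
    n_max: int = 1_000_000,
) -> int:
    """Smallest n at which a paired/one-sample t-test reaches ``power``."""
    if d <= 0:
        raise ValueError("effect size must be positive")
    if not 0 < power < 1:
        raise ValueError("power must lie in (0, 1)")
    for n in range(2, n_max + 1):
        if power_paired_t(n, d, alpha, tails) >= power:
            return n
    raise ValueError("requested power unreachable")
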