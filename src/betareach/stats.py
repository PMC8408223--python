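"""Group-level inference: permutation sensor maps and scalar tests.

Sensor maps use Monte-Carlo permutation t-tests (sign flips of per-subject
differences for the paired design, group-label exchanges with a Welch t for
the independent design), with the add-one p convention
``p = (1 + #{|t*| >= |t|}) / (n_perm + 1)`` and per-channel Bonferroni
correction (multiply by channel count, cap at 1).  A max-statistic
correction is available as an option.

Scalar tests: Wilcoxon signed-rank (exact sign-pattern enumeration for
n <= 12, tie-corrected normal approximation otherwise), Kruskal-Wallis with
tie correction, Spearman rank correlation (exact permutation p for n <= 8,
t approximation otherwise), and a classical two-way mixed ANOVA with
partial eta squared.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PermMapResult",
    "ScalarTestResult",
    "perm_ttest_paired",
    "perm_ttest_independent",
    "wilcoxon_signed_rank",
    "kruskal_wallis",
    "spearman",
    "mixed_anova",
]


@dataclass
class PermMapResult:
    t: np.ndarray
    p_corrected: np.ndarray
    significant: np.ndarray
    n_permutations: int
    alpha: float
    correction: str
    test: str

    def to_frame(self, channels=None) -> pd.DataFrame:
        ch = np.arange(self.t.size) if channels is None else np.asarray(channels)
        return pd.DataFrame(
            {
                "channel": ch,
                "t": self.t,
                "p_corrected": self.p_corrected,
                "significant": self.significant,
            }
        )


@dataclass
class ScalarTestResult:
    test: str
    statistic: float
    p: float
    effect_size: float | None = None
    detail: dict | None = None


def _paired_t(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    m = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / (sd / np.sqrt(n))
    return np.where(sd == 0, 0.0, t)


def _correct(p: np.ndarray, n_channels: int, correction: str) -> np.ndarray:
    if correction == "bonferroni":
        return np.minimum(1.0, p * n_channels)
    if correction == "none":
        return p
    raise ValueError(f"unknown correction {correction!r}")


def perm_ttest_paired(
    a: np.ndarray,
    b: np.ndarray,
    n_perm: int = 10000,
    alpha: float = 0.05,
    seed: int | None = None,
    correction: str = "bonferroni",
) -> PermMapResult:
    """Paired permutation t-map: null built by per-subject sign flips.

    ``a`` and ``b`` are (subjects x channels) maps from the same subjects.
    With ``correction='maxstat'`` p-values come from the permutation
    distribution of the maximum |t| over channels (no Bonferroni factor).
    """
    a, b = np.atleast_2d(np.asarray(a, float)), np.atleast_2d(np.asarray(b, float))
    if a.shape != b.shape:
        raise ValueError("paired maps must have identical shapes")
    n = a.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    d = a - b
    t_obs = _paired_t(d)
    rng = np.random.default_rng(seed)
    nch = d.shape[1]
    msq = (d**2).mean(axis=0)  # invariant under sign flips
    count = np.zeros(nch)
    max_count = np.zeros(nch)
    chunk = 2048
    done = 0
    while done < n_perm:
        k = min(chunk, n_perm - done)
        flips = rng.integers(0, 2, size=(k, n)) * 2 - 1
        m = flips @ d / n
        var = (msq[None, :] - m**2) * n / (n - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_star = m / np.sqrt(var / n)
        t_star = np.where(var <= 0, 0.0, np.abs(t_star))
        count += (t_star >= np.abs(t_obs)[None, :]).sum(axis=0)
        max_count += (t_star.max(axis=1)[:, None] >= np.abs(t_obs)[None, :]).sum(axis=0)
        done += k
    if correction == "maxstat":
        p_corr = (1.0 + max_count) / (n_perm + 1.0)
    else:
        p_raw = (1.0 + count) / (n_perm + 1.0)
        p_corr = _correct(p_raw, nch, correction)
    return PermMapResult(
        t=t_obs,
        p_corrected=p_corr,
        significant=p_corr <= alpha,
        n_permutations=n_perm,
        alpha=alpha,
        correction=correction,
        test="paired",
    )


def _welch_t(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    mx, my = x.mean(axis=0), y.mean(axis=0)
    vx, vy = x.var(axis=0, ddof=1), y.var(axis=0, ddof=1)
    den = np.sqrt(vx / x.shape[0] + vy / y.shape[0])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mx - my) / den
    return np.where(den == 0, 0.0, t)


def perm_ttest_independent(
    a: np.ndarray,
    b: np.ndarray,
    n_perm: int = 10000,
    alpha: float = 0.05,
    seed: int | None = None,
    correction: str = "bonferroni",
    pooled: bool = False,
) -> PermMapResult:
    """Independent-groups permutation t-map: null by group-label exchange.

    Welch's t by default (the groups may have unequal sizes and variances);
    set ``pooled=True`` for the pooled-variance statistic.
    """
    a, b = np.atleast_2d(np.asarray(a, float)), np.atleast_2d(np.asarray(b, float))
    if a.shape[1] != b.shape[1]:
        raise ValueError("groups must share the channel axis")
    na, nb = a.shape[0], b.shape[0]
    if na < 1 or nb < 1:
        raise ValueError("both groups must be non-empty")

    def stat(x, y):
        if not pooled:
            return _welch_t(x, y)
        sp2 = ((x.shape[0] - 1) * x.var(0, ddof=1) + (y.shape[0] - 1) * y.var(0, ddof=1)) / (
            x.shape[0] + y.shape[0] - 2
        )
        den = np.sqrt(sp2 * (1 / x.shape[0] + 1 / y.shape[0]))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (x.mean(0) - y.mean(0)) / den
        return np.where(den == 0, 0.0, t)

    t_obs = stat(a, b)
    z = np.concatenate([a, b], axis=0)
    n = na + nb
    rng = np.random.default_rng(seed)
    nch = z.shape[1]
    count = np.zeros(nch)
    max_count = np.zeros(nch)
    chunk = 512
    done = 0
    while done < n_perm:
        k = min(chunk, n_perm - done)
        idx = np.argsort(rng.random((k, n)), axis=1)
        t_star = np.empty((k, nch))
        for i in range(k):
            perm = z[idx[i]]
            t_star[i] = stat(perm[:na], perm[na:])
        t_star = np.abs(t_star)
        count += (t_star >= np.abs(t_obs)[None, :]).sum(axis=0)
        max_count += (t_star.max(axis=1)[:, None] >= np.abs(t_obs)[None, :]).sum(axis=0)
        done += k
    if correction == "maxstat":
        p_corr = (1.0 + max_count) / (n_perm + 1.0)
    else:
        p_raw = (1.0 + count) / (n_perm + 1.0)
        p_corr = _correct(p_raw, nch, correction)
    return PermMapResult(
        t=t_obs,
        p_corrected=p_corr,
        significant=p_corr <= alpha,
        n_permutations=n_perm,
        alpha=alpha,
        correction=correction,
        test="independent",
    )


def _signed_ranks(d: np.ndarray) -> np.ndarray:
    return sps.rankdata(np.abs(d))


def wilcoxon_signed_rank(
    x: np.ndarray, y: np.ndarray | None = None, exact_max_n: int = 12
) -> ScalarTestResult:
    """Wilcoxon signed-rank test on paired values (or precomputed differences).

    Zero differences are dropped.  For n <= ``exact_max_n`` the two-sided p
    is computed by exhaustive enumeration of all 2^n sign patterns over the
    (tie-averaged) ranks; otherwise the tie-corrected normal approximation
    is used.  Returns Z (normal-scale statistic) and p; the signed-rank sum
    W+ is in ``detail``.
    """
    x = np.asarray(x, float)
    d = x - np.asarray(y, float) if y is not None else x
    d = d[d != 0]
    n = d.size
    if n == 0:
        return ScalarTestResult(
            "wilcoxon", 0.0, 1.0, detail={"n": 0, "degenerate": True}
        )
    ranks = _signed_ranks(d)
    w_plus = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    _, counts = np.unique(np.abs(d), return_counts=True)
    tie_term = (counts**3 - counts).sum() / 48.0
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    z = 0.0 if sigma2 <= 0 else (w_plus - mu) / np.sqrt(sigma2)
    if n <= exact_max_n:
        obs = abs(w_plus - mu)
        # all 2^n sign patterns at once: bit k of row i says rank k is positive
        patterns = (
            np.arange(2**n)[:, None] >> np.arange(n)[None, :]
        ) & 1
        w_all = patterns @ ranks
        p = float(np.mean(np.abs(w_all - mu) >= obs - 1e-12))
        method = "exact"
    else:
        p = 2.0 * sps.norm.sf(abs(z))
        method = "normal"
    return ScalarTestResult(
        "wilcoxon",
        float(z),
        float(min(p, 1.0)),
        detail={"w_plus": w_plus, "n": n, "method": method},
    )


def kruskal_wallis(a: np.ndarray, b: np.ndarray) -> ScalarTestResult:
    """Two-group Kruskal-Wallis test (H, chi-square p with df=1, rank means)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.size < 1 or b.size < 1:
        raise ValueError("both groups must be non-empty")
    z = np.concatenate([a, b])
    n = z.size
    ranks = sps.rankdata(z)
    ra, rb = ranks[: a.size], ranks[a.size :]
    h = 12.0 / (n * (n + 1)) * (
        a.size * (ra.mean() - (n + 1) / 2) ** 2
        + b.size * (rb.mean() - (n + 1) / 2) ** 2
    )
    _, counts = np.unique(z, return_counts=True)
    tie_corr = 1.0 - (counts**3 - counts).sum() / (n**3 - n) if n > 1 else 1.0
    if tie_corr <= 0:  # all values identical
        return ScalarTestResult(
            "kruskal", 0.0, 1.0, detail={"rank_mean_a": ra.mean(), "rank_mean_b": rb.mean()}
        )
    h /= tie_corr
    p = float(sps.chi2.sf(h, df=1))
    return ScalarTestResult(
        "kruskal",
        float(h),
        p,
        detail={"rank_mean_a": float(ra.mean()), "rank_mean_b": float(rb.mean())},
    )


def spearman(x: np.ndarray, y: np.ndarray, exact_max_n: int = 8) -> ScalarTestResult:
    """Spearman rank correlation: Pearson r of tie-averaged ranks.

    Exact permutation p (all n! orderings of one rank vector) for
    n <= ``exact_max_n``; t approximation with n-2 df otherwise.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples, n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return ScalarTestResult(
            "spearman", np.nan, np.nan, detail={"degenerate": True}
        )
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = x.size
    if n <= exact_max_n:
        obs = abs(rho)
        perms = np.array(list(itertools.permutations(range(n))))
        ry_all = ry[perms]  # (n!, n)
        rxc = rx - rx.mean()
        ryc = ry_all - ry_all.mean(axis=1, keepdims=True)
        denom = np.sqrt((rxc**2).sum() * (ryc**2).sum(axis=1))
        rho_all = (ryc @ rxc) / denom
        p = float(np.mean(np.abs(rho_all) >= obs - 1e-12))
        method = "exact"
    else:
        t = rho * np.sqrt((n - 2) / max(1e-300, 1 - rho**2))
        p = float(2 * sps.t.sf(abs(t), df=n - 2))
        method = "t"
    return ScalarTestResult(
        "spearman", rho, float(min(p, 1.0)), detail={"n": n, "method": method}
    )


def mixed_anova(
    data: pd.DataFrame,
    dv: str,
    within: str,
    between: str,
    subject: str,
) -> dict[str, ScalarTestResult]:
    """Two-way mixed ANOVA (between-groups x within-subject) per effect.

    Returns ``ScalarTestResult`` objects keyed by effect name (the between
    factor, the within factor, and 'Interaction'), each carrying F, p and
    partial eta squared.  Requires complete cases (every subject observed at
    every within level).
    """
    import pingouin as pg

    counts = data.groupby(subject)[within].nunique()
    n_levels = data[within].nunique()
    if (counts != n_levels).any():
        raise ValueError("mixed_anova requires complete cases for every subject")
    table = pg.mixed_anova(
        data=data, dv=dv, within=within, between=between, subject=subject
    )
    out = {}
    for _, row in table.iterrows():
        out[row["Source"]] = ScalarTestResult(
            test="mixed_anova",
            statistic=float(row["F"]),
            p=float(row["p_unc"]),
            effect_size=float(row["np2"]),
            detail={"df1": float(row["DF1"]), "df2": float(row["DF2"])},
        )
    return out
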