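"""Count normalization and two-group negative-binomial differential expression.

The pipeline follows the classic count-based RNA-seq testing recipe:

* counts-per-million (CPM) scaling and a prevalence filter that keeps an
  entity only when its CPM reaches a floor in a minimum fraction of
  samples (default CPM >= 1 in at least 90% of samples);
* trimmed-mean-of-M-values (TMM) normalization factors, computed against
  a reference sample with 30% two-sided trimming on log-ratios (M) and
  5% on average log-abundance (A), weighting the retained M values by
  inverse asymptotic (delta-method) variances;
* a single common negative-binomial dispersion phi shared across genes,
  maximizing the conditional log-likelihood on library-size-equalized
  pseudo-counts (the conditional likelihood is dispersion-only because
  conditioning on the per-group sum removes the mean parameter);
* a two-sided exact test per gene conditioning on the total count, with
  group sums NB(size n_g/phi) and the Poisson/binomial limit at phi -> 0;
* Bonferroni and Benjamini-Hochberg adjustment (BH is the FDR column).

Fold changes are computed from prior-smoothed group mean CPMs so genes
with zero counts stay finite.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .quantify import CountTable


@dataclass(frozen=True)
class DesignInfo:
    """Two-group design.

    The control group (fold-change baseline) is ``control`` when given,
    otherwise the alphabetically first label — the same convention R's
    factor levels use, so swapping the two labels negates fold changes.
    """

    samples: tuple[str, ...]
    groups: tuple[str, ...]
    control: str | None = None

    def __post_init__(self) -> None:
        if len(self.samples) != len(self.groups):
            raise ValueError("samples and groups differ in length")
        if len(set(self.groups)) != 2:
            raise ValueError(f"exactly two groups required, got {sorted(set(self.groups))}")
        if self.control is not None and self.control not in self.groups:
            raise ValueError(f"control group {self.control!r} not in design")

    @property
    def group_names(self) -> tuple[str, str]:
        """(control, test)."""
        labels = sorted(set(self.groups))
        if self.control is not None and labels[0] != self.control:
            labels = [labels[1], labels[0]]
        return (labels[0], labels[1])

    def members(self, group: str) -> list[str]:
        return [s for s, g in zip(self.samples, self.groups) if g == group]


@dataclass(frozen=True)
class DeParams:
    fc_threshold: float = 1.5
    alpha: float = 0.05
    adjust: str = "bh"           # which adjusted p drives `significant`
    prior_count: float = 0.125

    def __post_init__(self) -> None:
        if self.adjust not in ("bh", "bonferroni", "raw"):
            raise ValueError(f"unknown adjustment {self.adjust!r}")


@dataclass
class DETable:
    level: str
    table: pd.DataFrame  # columns: log2_fc, avg_log2_cpm, p_raw, p_bonferroni, p_bh, significant

    def to_tsv(self) -> str:
        out = self.table.copy()
        out.insert(0, "level", self.level)
        out.index.name = "name"
        return out.to_csv(sep="\t")


def cpm(
    counts: CountTable | pd.DataFrame,
    lib_sizes: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Counts per million; ``lib_sizes`` default to raw column sums."""
    frame = counts.counts if isinstance(counts, CountTable) else counts
    if lib_sizes is None:
        lib_sizes = frame.sum(axis=0).to_numpy(dtype=float)
    lib = np.asarray(lib_sizes, dtype=float)
    if (lib <= 0).any():
        raise ValueError("library sizes must be positive")
    return frame / lib * 1e6


def filter_low_counts(
    counts: CountTable,
    min_cpm: float = 1.0,
    min_fraction: float = 0.9,
) -> tuple[CountTable, list[str]]:
    """Keep entities with CPM >= min_cpm in at least ceil(min_fraction * n) samples."""
    frame = counts.counts
    if frame.shape[1] < 1:
        raise ValueError("at least one sample required")
    needed = math.ceil(min_fraction * frame.shape[1])
    ok = (cpm(frame) >= min_cpm).sum(axis=1) >= needed
    kept = CountTable(level=counts.level, counts=frame.loc[ok])
    removed = list(frame.index[~ok])
    return kept, removed


def _upper_quartile(frame: pd.DataFrame) -> np.ndarray:
    lib = frame.sum(axis=0).to_numpy(dtype=float)
    return np.array(
        [np.quantile(frame.iloc[:, j].to_numpy(dtype=float) / lib[j], 0.75)
         for j in range(frame.shape[1])]
    )


def _tmm_pair(
    obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
    logratio_trim: float = 0.3, abundance_trim: float = 0.05,
) -> float:
    mask = (obs > 0) & (ref > 0)
    obs, ref = obs[mask].astype(float), ref[mask].astype(float)
    if obs.size == 0:
        warnings.warn("no usable genes for TMM pair; factor set to 1")
        return 1.0
    p_obs, p_ref = obs / n_obs, ref / n_ref
    M = np.log2(p_obs / p_ref)
    A = 0.5 * np.log2(p_obs * p_ref)
    v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    fin = np.isfinite(M) & np.isfinite(A)
    M, A, v = M[fin], A[fin], v[fin]
    if M.size == 0 or np.max(np.abs(M)) < 1e-6:
        return 1.0
    n = M.size
    lo_m = math.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = math.floor(n * abundance_trim) + 1
    hi_a = n + 1 - lo_a
    rank_m = stats.rankdata(M)
    rank_a = stats.rankdata(A)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any() or v[keep].min() <= 0:
        return 1.0
    f = np.sum(M[keep] / v[keep]) / np.sum(1.0 / v[keep])
    return float(2.0 ** f)


def tmm_factors(
    counts: CountTable | pd.DataFrame, ref_sample: str | None = None
) -> pd.Series:
    """Per-sample TMM normalization factors, geometric mean 1."""
    frame = counts.counts if isinstance(counts, CountTable) else counts
    if frame.shape[1] < 2:
        raise ValueError("TMM requires at least two samples")
    lib = frame.sum(axis=0).to_numpy(dtype=float)
    if (lib <= 0).any():
        raise ValueError("every sample needs a positive library size")
    if ref_sample is None:
        uq = _upper_quartile(frame)
        ref_j = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        ref_j = list(frame.columns).index(ref_sample)
    ref = frame.iloc[:, ref_j].to_numpy()
    factors = np.array(
        [
            1.0 if j == ref_j else _tmm_pair(
                frame.iloc[:, j].to_numpy(), ref, lib[j], lib[ref_j]
            )
            for j in range(frame.shape[1])
        ]
    )
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=frame.columns, name="tmm_factor")


def effective_lib_sizes(
    counts: CountTable | pd.DataFrame, factors: pd.Series | None = None
) -> pd.Series:
    frame = counts.counts if isinstance(counts, CountTable) else counts
    lib = frame.sum(axis=0).astype(float)
    if factors is None:
        factors = tmm_factors(frame)
    return lib * factors


def _pseudo_counts(frame: pd.DataFrame, efflib: pd.Series) -> tuple[pd.DataFrame, float]:
    """Scale each column to the geometric-mean effective library size."""
    common = float(np.exp(np.mean(np.log(efflib.to_numpy(dtype=float)))))
    pseudo = frame.astype(float) * (common / efflib.to_numpy(dtype=float))
    return pseudo, common


def _group_cond_loglik(pseudo: np.ndarray, phi: float) -> float:
    """Conditional NB log-likelihood of one group's genes x samples block."""
    r = 1.0 / phi
    n = pseudo.shape[1]
    t = pseudo.sum(axis=1)
    ll = (
        gammaln(pseudo + r).sum(axis=1)
        - n * gammaln(r)
        + gammaln(n * r)
        - gammaln(t + n * r)
    )
    return float(ll.sum())


def estimate_common_dispersion(
    counts: CountTable | pd.DataFrame,
    design: DesignInfo,
    efflib: pd.Series | None = None,
    bounds: tuple[float, float] = (1e-6, 4.0),
) -> float:
    """Common NB dispersion maximizing the conditional likelihood.

    Counts are first equalized to a common library size (quantile-adjusted
    pseudo-counts); the conditional likelihood given each group's total is
    then a function of the dispersion alone and is maximized numerically
    over ``bounds``.
    """
    frame = counts.counts if isinstance(counts, CountTable) else counts
    if frame.to_numpy().sum() == 0:
        raise ValueError("all-zero count matrix")
    if efflib is None:
        efflib = effective_lib_sizes(frame)
    pseudo, _ = _pseudo_counts(frame, efflib)
    blocks = [
        pseudo[design.members(g)].to_numpy(dtype=float)
        for g in design.group_names
    ]

    def neg_ll(phi: float) -> float:
        return -sum(_group_cond_loglik(b, phi) for b in blocks)

    res = optimize.minimize_scalar(neg_ll, bounds=bounds, method="bounded")
    phi = float(res.x)
    # boundary check: likelihood may be monotone decreasing (no overdispersion)
    if neg_ll(bounds[0]) <= res.fun:
        phi = bounds[0]
    return max(phi, 0.0)


def exact_nb_test(
    sum_a: int, sum_b: int, n_a: int, n_b: int, phi: float
) -> float:
    """Two-sided exact test of equal means given the total count.

    Group sums are NB with sizes ``n_a/phi`` and ``n_b/phi`` under the
    null of a shared per-sample mean; the p-value sums, over all splits
    (a, t-a) of the observed total t, the probabilities not exceeding the
    observed split's probability.  At phi -> 0 this is the exact binomial
    split test.
    """
    if phi < 0:
        raise ValueError("dispersion must be non-negative")
    t = int(round(sum_a + sum_b))
    if t == 0:
        return 1.0
    a_obs = int(round(sum_a))
    a = np.arange(t + 1)
    if phi < 1e-8:
        logp = stats.binom.logpmf(a, t, n_a / (n_a + n_b))
    else:
        mu = t / (n_a + n_b)          # common per-sample mean on the pseudo scale
        r_a, r_b = n_a / phi, n_b / phi
        mean_a, mean_b = n_a * mu, n_b * mu
        p_a = r_a / (r_a + mean_a)
        p_b = r_b / (r_b + mean_b)
        logp = stats.nbinom.logpmf(a, r_a, p_a) + stats.nbinom.logpmf(t - a, r_b, p_b)
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    p = float(probs[probs <= probs[a_obs] * (1.0 + 1e-10)].sum())
    return min(max(p, np.nextafter(0, 1)), 1.0)


def adjust_pvalues(p: Sequence[float], method: str = "bh") -> np.ndarray:
    """Bonferroni or Benjamini-Hochberg adjustment, input order preserved."""
    arr = np.asarray(p, dtype=float)
    if ((arr < 0) | (arr > 1)).any() or np.isnan(arr).any():
        raise ValueError("p-values must lie in [0, 1]")
    if arr.size == 0:
        return arr.copy()
    key = {"bh": "fdr_bh", "bonferroni": "bonferroni"}[method]
    return multipletests(arr, method=key)[1]


def _smoothed_log2_cpm(
    frame: pd.DataFrame, efflib: pd.Series, prior: float
) -> pd.DataFrame:
    lib = efflib.to_numpy(dtype=float)
    prior_s = prior * lib / lib.mean()
    return np.log2((frame.astype(float) + prior_s) / (lib + 2 * prior_s) * 1e6)


def run_de(
    counts: CountTable,
    design: DesignInfo,
    params: DeParams = DeParams(),
) -> DETable:
    """TMM -> common dispersion -> per-gene exact test -> adjusted p-values.

    ``log2_fc`` is test-over-control (second group over first) from
    prior-smoothed group mean CPMs.
    """
    frame = counts.counts[list(design.samples)]
    ctrl, test = design.group_names
    for g in (ctrl, test):
        if frame[design.members(g)].to_numpy().sum() == 0:
            raise ValueError(f"group {g!r} has zero total counts")
    factors = tmm_factors(frame)
    efflib = effective_lib_sizes(frame, factors)
    phi = estimate_common_dispersion(frame, design, efflib=efflib)
    pseudo, _ = _pseudo_counts(frame, efflib)
    rounded = np.round(pseudo.to_numpy(dtype=float))  # half-to-even
    ctrl_ix = [list(frame.columns).index(s) for s in design.members(ctrl)]
    test_ix = [list(frame.columns).index(s) for s in design.members(test)]
    n_a, n_b = len(ctrl_ix), len(test_ix)
    p_raw = np.array(
        [
            exact_nb_test(
                int(rounded[g, ctrl_ix].sum()), int(rounded[g, test_ix].sum()),
                n_a, n_b, phi,
            )
            for g in range(rounded.shape[0])
        ]
    )
    log2cpm = _smoothed_log2_cpm(frame, efflib, params.prior_count)
    log2_fc = (
        log2cpm[design.members(test)].mean(axis=1)
        - log2cpm[design.members(ctrl)].mean(axis=1)
    )
    avg_log2_cpm = log2cpm.mean(axis=1)
    p_bonf = adjust_pvalues(p_raw, "bonferroni")
    p_bh = adjust_pvalues(p_raw, "bh")
    p_sig = {"bh": p_bh, "bonferroni": p_bonf, "raw": p_raw}[params.adjust]
    significant = (np.abs(log2_fc) > np.log2(params.fc_threshold)) & (
        p_sig < params.alpha
    )
    table = pd.DataFrame(
        {
            "log2_fc": log2_fc,
            "avg_log2_cpm": avg_log2_cpm,
            "p_raw": p_raw,
            "p_bonferroni": p_bonf,
            "p_bh": p_bh,
            "significant": significant,
        },
        index=frame.index,
    )
    return DETable(level=counts.level, table=table)
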