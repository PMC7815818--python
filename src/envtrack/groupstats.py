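"""Group-level statistics.

EEG SNR proxy (post/pre stimulus RMS ratio), rationalized arcsine transform
of comprehension accuracy, 2x2 mixed ANOVA with generalized eta squared, and
cluster-based permutation comparison of TRF time courses using Wilcoxon
rank-sum statistics.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import f as f_dist
from scipy.stats import norm, rankdata

from .preprocess import EEGEpochs

__all__ = [
    "SNRRecord",
    "AnovaTable",
    "ClusterResult",
    "eeg_snr",
    "rau_transform",
    "mixed_anova_2x2",
    "ranksum_z",
    "cluster_permutation_trf",
]

_EPS = 1e-12


@dataclass
class SNRRecord:
    subject_id: str
    group: str
    narrative: str
    snr: float
    post_window_s: tuple[float, float] = (1.6, 55.0)
    pre_window_s: tuple[float, float] = (-2.6, -1.6)

    def __post_init__(self) -> None:
        if self.snr <= 0:
            raise ValueError("snr must be > 0")


def eeg_snr(
    epochs: EEGEpochs,
    post_window_s: tuple[float, float] = (1.6, 55.0),
    pre_window_s: tuple[float, float] = (-2.6, -1.6),
    narrative: str = "narrative1",
) -> SNRRecord:
    """RMS(post-onset) / RMS(pre-onset), pooled over channels and tracks."""
    t0, t1 = epochs.epoch_window_s
    for name, (a, b) in (("post", post_window_s), ("pre", pre_window_s)):
        if not (t0 <= a < b <= t1):
            raise ValueError(f"{name} window ({a}, {b}) outside epoch ({t0}, {t1})")
    if pre_window_s[1] > 0:
        raise ValueError("pre window must precede stimulus onset")

    def _slice(win):
        i0 = epochs.onset_sample + int(round(win[0] * epochs.fs))
        i1 = epochs.onset_sample + int(round(win[1] * epochs.fs))
        return epochs.data[:, i0:i1, :]

    rms_post = np.sqrt((_slice(post_window_s) ** 2).mean())
    rms_pre = np.sqrt((_slice(pre_window_s) ** 2).mean())
    if rms_pre == 0:
        raise ValueError("degenerate input: zero pre-stimulus RMS")
    return SNRRecord(
        subject_id=epochs.subject_id,
        group=epochs.group,
        narrative=narrative,
        snr=float(rms_post / rms_pre),
        post_window_s=post_window_s,
        pre_window_s=pre_window_s,
    )


def rau_transform(correct, total):
    """Rationalized arcsine units (Studebaker 1985).

    theta = asin(sqrt(x/(n+1))) + asin(sqrt((x+1)/(n+1))); RAU = (146/pi)*theta - 23.
    """
    correct = np.asarray(correct, dtype=float)
    total = np.asarray(total, dtype=float)
    if np.any(total < 1):
        raise ValueError("total must be >= 1")
    if np.any((correct < 0) | (correct > total)):
        raise ValueError("need 0 <= correct <= total")
    theta = np.arcsin(np.sqrt(correct / (total + 1.0))) + np.arcsin(
        np.sqrt((correct + 1.0) / (total + 1.0))
    )
    out = (146.0 / np.pi) * theta - 23.0
    return out.item() if out.ndim == 0 else out


@dataclass
class AnovaTable:
    """Mixed 2x2 ANOVA: each effect carries F, df, p, and generalized eta^2."""

    effects: dict

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {"effect": name, "F": e["F"], "df_num": e["df"][0], "df_den": e["df"][1],
                 "p": e["p"], "ges": e["ges"], "degenerate": e.get("degenerate", False)}
                for name, e in self.effects.items()
            ]
        )


def mixed_anova_2x2(values: np.ndarray, group_labels) -> AnovaTable:
    """Mixed ANOVA: 2-level between factor (group) x 2-level within factor.

    ``values`` is subject x 2 (one column per within-subject condition),
    ``group_labels`` assigns each subject to one of exactly two groups.
    Between effect is tested against subjects-within-groups; within and
    interaction effects against the subject x condition residual.
    Generalized eta squared follows the Olejnik-Algina convention
    (denominator: effect SS plus all subject-linked error SS).
    """
    Y = np.asarray(values, dtype=float)
    g = np.asarray(group_labels)
    if Y.ndim != 2 or Y.shape[1] != 2:
        raise ValueError("values must be subject x 2 (two within-subject conditions)")
    if np.any(~np.isfinite(Y)):
        raise ValueError("incomplete design: missing cells")
    levels = np.unique(g)
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {len(levels)}")
    counts = np.array([(g == lv).sum() for lv in levels])
    if np.any(counts < 2):
        raise ValueError("need >= 2 subjects per group")

    N = Y.shape[0]
    grand = Y.mean()
    subj_means = Y.mean(axis=1)
    group_means = np.array([Y[g == lv].mean() for lv in levels])
    cond_means = Y.mean(axis=0)
    cell_means = np.array([[Y[g == lv, c].mean() for c in (0, 1)] for lv in levels])

    ss_total = ((Y - grand) ** 2).sum()
    ss_between_subj = 2.0 * ((subj_means - grand) ** 2).sum()
    ss_group = 2.0 * (counts * (group_means - grand) ** 2).sum()
    ss_subj_within = ss_between_subj - ss_group
    ss_within = ss_total - ss_between_subj
    ss_cond = N * ((cond_means - grand) ** 2).sum()
    ss_inter = 0.0
    for gi, lv in enumerate(levels):
        for c in (0, 1):
            ss_inter += counts[gi] * (
                cell_means[gi, c] - group_means[gi] - cond_means[c] + grand
            ) ** 2
    ss_res = ss_within - ss_cond - ss_inter

    df_den = N - 2
    ms_subj = ss_subj_within / df_den
    ms_res = max(ss_res, 0.0) / df_den
    scale = max(ss_total, 1.0)

    def _entry(ss_eff, ms_err):
        degenerate = False
        if ss_eff <= _EPS * scale:
            F, p = 0.0, 1.0
        elif ms_err <= _EPS * scale:
            F, p, degenerate = np.inf, 0.0, True
        else:
            F = (ss_eff / 1.0) / ms_err
            p = float(f_dist.sf(F, 1, df_den))
        denom = ss_eff + ss_subj_within + max(ss_res, 0.0)
        ges = ss_eff / denom if denom > 0 else 0.0
        return {"F": F, "df": (1, df_den), "p": p, "ges": float(ges),
                "degenerate": degenerate}

    return AnovaTable(
        effects={
            "group": _entry(ss_group, ms_subj),
            "narrative": _entry(ss_cond, ms_res),
            "group:narrative": _entry(ss_inter, ms_res),
        }
    )


def ranksum_z(a: np.ndarray, b: np.ndarray) -> float:
    """Two-tailed Wilcoxon rank-sum z (mid-ranks, tie-corrected variance, no cc)."""
    z, _ = _ranksum_z_many(
        np.concatenate([np.atleast_1d(a), np.atleast_1d(b)])[:, None], len(np.atleast_1d(a))
    )
    return float(z[0])


def _ranksum_z_many(pooled: np.ndarray, n_a: int):
    """z statistic per column for group A = first ``n_a`` rows of ``pooled``.

    Returns (z per column, ranks matrix) using the tie-corrected normal
    approximation, which equals exact enumeration-based standardization.
    """
    N, n_cols = pooled.shape
    n_b = N - n_a
    R = rankdata(pooled, axis=0)
    W = R[:n_a].sum(axis=0)
    mu = n_a * (N + 1) / 2.0
    tie_term = np.empty(n_cols)
    for c in range(n_cols):
        _, cnt = np.unique(pooled[:, c], return_counts=True)
        tie_term[c] = (cnt**3 - cnt).sum()
    var = (n_a * n_b / 12.0) * ((N + 1) - tie_term / (N * (N - 1.0)))
    sd = np.sqrt(np.maximum(var, _EPS))
    return (W - mu) / sd, R


@dataclass
class ClusterResult:
    clusters: list  # [{"start", "end", "lag_range_ms", "mass", "p"}]
    zmap: np.ndarray
    sig_mask: np.ndarray
    n_perm: int
    null_max: np.ndarray | None = None


def _find_clusters(z: np.ndarray, z_crit: float):
    """Maximal contiguous runs with |z| > z_crit; mass = sum of z over the run."""
    above = np.abs(z) > z_crit
    clusters = []
    i = 0
    n = len(z)
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            clusters.append((i, j, float(z[i : j + 1].sum())))
            i = j + 1
        else:
            i += 1
    return clusters


def cluster_permutation_trf(
    trfs_group_a: np.ndarray,
    trfs_group_b: np.ndarray,
    n_perm: int = 1000,
    alpha_cluster: float = 0.05,
    seed: int | np.random.Generator = 0,
    *,
    lags_ms: np.ndarray | None = None,
    alpha_sig: float = 0.05,
    return_null: bool = False,
) -> ClusterResult:
    """Cluster-based permutation comparison of two groups' TRF time courses.

    Per lag sample, a two-tailed Wilcoxon rank-sum z between groups; candidate
    clusters are maximal contiguous runs with |z| above the alpha_cluster
    normal quantile; cluster mass is the summed z. The null distribution is
    the maximum |mass| over clusters from random relabelings of group
    membership; cluster p = proportion of null maxima >= observed |mass|.
    """
    A = np.atleast_2d(np.asarray(trfs_group_a, dtype=float))
    B = np.atleast_2d(np.asarray(trfs_group_b, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise ValueError("unequal lag axes")
    if A.shape[0] < 2 or B.shape[0] < 2:
        raise ValueError("need >= 2 subjects per group")
    if n_perm < 100:
        raise ValueError("n_perm < 100 gives an unstable null; use >= 100")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    n_a, n_b = A.shape[0], B.shape[0]
    N = n_a + n_b
    pooled = np.vstack([A, B])  # (N, n_lags)
    z_obs, R = _ranksum_z_many(pooled, n_a)
    z_crit = float(norm.ppf(1.0 - alpha_cluster / 2.0))
    obs_clusters = _find_clusters(z_obs, z_crit)

    # permutation null: relabel group membership; ranks per lag are invariant,
    # so only the selection of rows entering the rank sum changes.
    n_lags = pooled.shape[1]
    mu = n_a * (N + 1) / 2.0
    tie_term = np.empty(n_lags)
    for c in range(n_lags):
        _, cnt = np.unique(pooled[:, c], return_counts=True)
        tie_term[c] = (cnt**3 - cnt).sum()
    sd = np.sqrt(np.maximum((n_a * n_b / 12.0) * ((N + 1) - tie_term / (N * (N - 1.0))), _EPS))

    sel = np.zeros((n_perm, N))
    order = np.argsort(rng.random((n_perm, N)), axis=1)[:, :n_a]
    np.put_along_axis(sel, order, 1.0, axis=1)
    W_perm = sel @ R  # (n_perm, n_lags)
    Z_perm = (W_perm - mu) / sd

    null_max = np.zeros(n_perm)
    for p in range(n_perm):
        masses = [abs(m) for _, _, m in _find_clusters(Z_perm[p], z_crit)]
        null_max[p] = max(masses) if masses else 0.0

    if lags_ms is None:
        lags_ms = np.arange(n_lags, dtype=float)
    clusters = []
    sig_mask = np.zeros(n_lags, dtype=bool)
    for i, j, mass in obs_clusters:
        p_val = float((null_max >= abs(mass)).mean())
        clusters.append(
            {"start": i, "end": j, "lag_range_ms": (float(lags_ms[i]), float(lags_ms[j])),
             "mass": mass, "p": p_val}
        )
        if p_val < alpha_sig:
            sig_mask[i : j + 1] = True

    return ClusterResult(
        clusters=clusters,
        zmap=z_obs,
        sig_mask=sig_mask,
        n_perm=n_perm,
        null_max=null_max if return_null else None,
    )
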