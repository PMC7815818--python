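"""Property-based validation battery on synthetic data with known ground truth.

Each function recomputes one end-to-end quantity from scratch — ridge-solver
agreement with an explicit normal-equations oracle, kernel recovery at high
SNR, permutation chance-level calibration, cluster-test type-I error and
effect recovery, the theta/delta group dissociation, filterbank analytics,
and the RAU/ANOVA micro-oracles. Used by the acceptance test suite and the
standalone acceptance report script.

All scales are reduced relative to the emulated study (shorter tracks, fewer
bands/channels) so the whole battery runs on one CPU in minutes; the measured
quantities are scale-invariant properties of the methods.
"""
from __future__ import annotations

import hashlib

import numpy as np

from . import groupstats as gs
from . import preprocess as pp
from . import synthdata as sd
from . import trf
from .envelope import (
    FilterbankSpec,
    erb_bandwidth,
    erb_center_frequencies,
    erb_rate,
    gammatone_filterbank,
    multiband_envelope,
)
from .envelope import AudioTrack


def _subseed(*parts) -> int:
    """Stable integer sub-seed from mixed int/str parts."""
    return int.from_bytes(hashlib.sha256(repr(parts).encode()).digest()[:8], "little")


# --- 1. ridge oracle equivalence --------------------------------------------

def _ridge_normal_equations_oracle(X, Y, lam):
    """Independent route: explicit matrix inversion of the penalized normal
    equations (intercept unpenalized, lambda scaled by trace(XtX)/ncols)."""
    ncols = X.shape[1]
    P = np.eye(ncols)
    P[0, 0] = 0.0
    m = np.trace(X.T @ X) / ncols
    return np.linalg.inv(X.T @ X + lam * m * P) @ (X.T @ Y)


def ridge_oracle_equivalence(seed: int = 0, n_systems: int = 20) -> float:
    """Max relative error of fit_ridge vs the inversion oracle over random
    small systems (<= 50 x 10) at lambda in {0, 1, 100}."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_systems):
        n = int(rng.integers(12, 51))
        p = int(rng.integers(2, 11))
        X = np.c_[np.ones(n), rng.standard_normal((n, p - 1))]
        Y = rng.standard_normal((n, 2))
        for lam in (0.0, 1.0, 100.0):
            model = trf.fit_ridge(X, Y, lam)
            W = np.r_[model.intercept[None, :], model.flat_weights()]
            oracle = _ridge_normal_equations_oracle(X, Y, lam)
            worst = max(worst, np.linalg.norm(W - oracle) / np.linalg.norm(oracle))
    return worst


# --- 2. kernel recovery -------------------------------------------------------

def kernel_recovery(seed: int = 0) -> dict:
    """Noiseless-limit forward/inverse consistency: snr 60 dB, 5 tracks x 20 s,
    8 channels; lambda -> 0 TRF vs ground-truth kernel."""
    cfg = sd.SimulationConfig(
        n_tracks=5, track_duration_s=20.0, n_channels=8, snr_db=60.0,
        seed=seed, n_bands=16,
    )
    window = trf.LagWindow(fs=cfg.eeg_fs)
    rng = np.random.default_rng(seed)
    stimuli = [
        sd.make_syllabic_stimulus(cfg.track_duration_s, cfg.audio_fs,
                                  cfg.syllable_rate_hz, rng)
        for _ in range(cfg.n_tracks)
    ]
    envs = [multiband_envelope(s, cfg.filterbank, fs_out=cfg.eeg_fs) for s in stimuli]
    gram = trf.DesignGram(trf.prepare_designs(envs, window))
    kernel = sd.default_kernel(window, cfg.n_bands, cfg.n_channels, seed=rng)
    epochs = sd.simulate_subject_eeg([], kernel, cfg, seed=rng, envelopes=envs,
                                     window=window)
    model = trf.fit_subject_trf(envs, epochs, window, lam=0.0, gram=gram)
    per_channel_r = np.array([
        np.corrcoef(model.weights[:, :, c].ravel(), kernel.weights[:, :, c].ravel())[0, 1]
        for c in range(cfg.n_channels)
    ])
    nrmse = float(
        np.linalg.norm(model.weights - kernel.weights) / np.linalg.norm(kernel.weights)
    )
    return {"min_channel_r": float(per_channel_r.min()), "nrmse": nrmse}


# --- 3. chance-level calibration ---------------------------------------------

def chance_level_calibration(
    seed: int = 0, n_replicates: int = 200, n_perm: int = 200
) -> dict:
    """Fraction of stimulus-independent-noise replicates whose matched
    grand-mean tracking exceeds the permutation 97.5th-percentile threshold
    (nominal 0.025)."""
    cfg = sd.SimulationConfig(
        n_tracks=5, track_duration_s=8.0, n_channels=4, snr_db=0.0, seed=seed,
        n_bands=4, f_low=250.0, f_high=4000.0,
    )
    window = trf.LagWindow(fs=cfg.eeg_fs)
    rng = np.random.default_rng(seed)
    stimuli = [
        sd.make_syllabic_stimulus(cfg.track_duration_s, cfg.audio_fs, 4.5, rng)
        for _ in range(cfg.n_tracks)
    ]
    envs = [multiband_envelope(s, cfg.filterbank, fs_out=cfg.eeg_fs) for s in stimuli]
    gram = trf.DesignGram(trf.prepare_designs(envs, window))
    lam = 10.0
    n_exceed = 0
    for rep in range(n_replicates):
        rep_rng = np.random.default_rng(_subseed(seed, rep))
        Y = [rep_rng.standard_normal((n, cfg.n_channels)) for n in gram.nsamp]
        matched = trf.crossval_tracking(None, Y, window, [lam], gram=gram).r_mean
        level = trf.permutation_chance_level(None, Y, window, lam, n_perm,
                                             seed=rep_rng, gram=gram)
        n_exceed += matched > level
    return {
        "exceedance_rate": n_exceed / n_replicates,
        "n_replicates": n_replicates,
        "nominal": 0.025,
    }


# --- 4. cluster test: type-I error and effect recovery ------------------------

def cluster_test_validation(
    seed: int = 0, n_seeds: int = 20, n_perm: int = 500, n_lags: int = 71
) -> dict:
    """(a) any-significant-cluster rate for two groups from the same generator;
    (b) recovery of a constructed 50-150 ms offset effect."""
    n_sig = 0
    for rep in range(n_seeds):
        rng = np.random.default_rng(_subseed(seed, rep))
        A = rng.standard_normal((8, n_lags))
        B = rng.standard_normal((8, n_lags))
        res = gs.cluster_permutation_trf(A, B, n_perm=n_perm, seed=rng)
        n_sig += any(c["p"] < 0.05 for c in res.clusters)

    lags_ms = np.linspace(-100.0, 450.0, n_lags)
    rng = np.random.default_rng(_subseed(seed, "effect"))
    A = rng.standard_normal((8, n_lags))
    B = rng.standard_normal((8, n_lags))
    B[:, (lags_ms >= 50.0) & (lags_ms <= 150.0)] += 4.0
    res = gs.cluster_permutation_trf(A, B, n_perm=n_perm, seed=rng, lags_ms=lags_ms)
    sig = [c for c in res.clusters if c["p"] < 0.05]
    step = float(lags_ms[1] - lags_ms[0])
    if sig:
        best = max(sig, key=lambda c: abs(c["mass"]))
        recovered = (
            best["lag_range_ms"][0] <= 50.0 + 2 * step
            and best["lag_range_ms"][1] >= 150.0 - 2 * step
        )
    else:
        recovered = False
    return {
        "type1_rate": n_sig / n_seeds,
        "n_seeds": n_seeds,
        "effect_recovered": bool(recovered),
    }


# --- 5. headline dissociation, synthetic analogue -----------------------------

def _narrative_features(seed: int, cfg: sd.SimulationConfig, window: trf.LagWindow,
                        n_narratives: int = 2):
    """Fixed stimuli (shared by all subjects, like the study's narratives)."""
    narratives = []
    for nar in range(n_narratives):
        rng = np.random.default_rng(_subseed(seed, "narrative", nar))
        stims = [
            sd.make_syllabic_stimulus(cfg.track_duration_s, cfg.audio_fs,
                                      cfg.syllable_rate_hz, rng)
            for _ in range(cfg.n_tracks)
        ]
        envs = [multiband_envelope(s, cfg.filterbank, fs_out=cfg.eeg_fs)
                for s in stims]
        narratives.append((envs, trf.DesignGram(trf.prepare_designs(envs, window))))
    return narratives


def dissociation_analysis(
    seed: int = 0,
    n_seeds: int = 10,
    theta_gain: float = 2.0,
    n_subjects_per_group: int = 10,
    lambda_grid=None,
) -> dict:
    """Simulated lvPPA-like (theta_gain) vs control groups, 2 narratives:
    per-seed 2x2 mixed ANOVA on theta- and delta-band tracking metrics.

    Returns the rate of significant (p < 0.05) group effects per band over
    seeds, the ANOVA dfs, and mean tracking metrics per group.
    """
    if lambda_grid is None:
        lambda_grid = 10.0 ** np.arange(0, 7)
    cfg = sd.SimulationConfig(
        n_tracks=5, track_duration_s=10.0, n_channels=8, snr_db=-11.0,
        seed=seed, n_bands=8,
    )
    window = trf.LagWindow(fs=cfg.eeg_fs)
    narratives = _narrative_features(seed, cfg, window)

    bands = ("delta", "theta")
    sig = {b: 0 for b in bands}
    df_seen = None
    means = {b: {"lvPPA": [], "HC": []} for b in bands}
    n_tot = 2 * n_subjects_per_group
    for rep in range(n_seeds):
        rng = np.random.default_rng(_subseed(seed, "subjects", rep))
        vals = {b: np.zeros((n_tot, 2)) for b in bands}
        labels = ["lvPPA"] * n_subjects_per_group + ["HC"] * n_subjects_per_group
        for si, grp in enumerate(labels):
            gain = theta_gain if grp == "lvPPA" else 1.0
            kern = sd.default_kernel(window, cfg.n_bands, cfg.n_channels,
                                     seed=rng, theta_gain=gain)
            for nar, (envs, gram) in enumerate(narratives):
                ep = sd.simulate_subject_eeg([], kern, cfg, seed=rng,
                                             envelopes=envs, window=window)
                ep = pp.common_average_reference(ep)
                for band in bands:
                    bep = pp.zscore_subject(pp.bandpass(ep, pp.DEFAULT_BANDS[band]))
                    res = trf.crossval_tracking(envs, bep, window, lambda_grid,
                                                gram=gram)
                    vals[band][si, nar] = res.r_mean
        for band in bands:
            table = gs.mixed_anova_2x2(vals[band], labels)
            sig[band] += table.effects["group"]["p"] < 0.05
            df_seen = table.effects["group"]["df"]
            means[band]["lvPPA"].append(vals[band][:n_subjects_per_group].mean())
            means[band]["HC"].append(vals[band][n_subjects_per_group:].mean())
    return {
        "theta_sig_rate": sig["theta"] / n_seeds,
        "delta_sig_rate": sig["delta"] / n_seeds,
        "df": df_seen,
        "n_seeds": n_seeds,
        "theta_r_lvppa": float(np.mean(means["theta"]["lvPPA"])),
        "theta_r_hc": float(np.mean(means["theta"]["HC"])),
        "delta_r_lvppa": float(np.mean(means["delta"]["lvPPA"])),
        "delta_r_hc": float(np.mean(means["delta"]["HC"])),
    }


# --- 6. filterbank analytics --------------------------------------------------

def filterbank_analytics() -> dict:
    """ERB-spacing exactness and gammatone -3 dB bandwidths vs ERB(f_c)."""
    spec = FilterbankSpec(16, 250.0, 8000.0)
    fc = erb_center_frequencies(spec)
    rates = erb_rate(fc)
    steps = np.diff(rates)
    spacing_dev = float(np.max(np.abs(steps - steps[0])) / steps[0])

    fs = 32000
    imp = AudioTrack(np.r_[1.0, np.zeros(fs - 1)], float(fs))
    H = np.abs(np.fft.rfft(gammatone_filterbank(imp, spec), axis=1))
    f = np.fft.rfftfreq(fs, 1.0 / fs)
    worst_bw_dev = 0.0
    for i in range(spec.n_bands):
        above = f[H[i] > H[i].max() / np.sqrt(2.0)]
        bw = above.max() - above.min()
        worst_bw_dev = max(worst_bw_dev, abs(bw / erb_bandwidth(fc[i]) - 1.0))
    return {
        "first_center_hz": float(fc[0]),
        "last_center_hz": float(fc[-1]),
        "max_spacing_rel_dev": spacing_dev,
        "max_bandwidth_rel_dev": float(worst_bw_dev),
    }


# --- 7. RAU and ANOVA micro-oracles ------------------------------------------

def micro_oracles(seed: int = 0) -> dict:
    """RAU vs direct formula on a grid; mixed ANOVA vs hand SS decomposition
    on a fixed 20-subject fixture."""
    worst_rau = 0.0
    for total in (10, 25, 30, 100):
        for correct in range(total + 1):
            theta = np.arcsin(np.sqrt(correct / (total + 1.0))) + np.arcsin(
                np.sqrt((correct + 1.0) / (total + 1.0))
            )
            expected = (146.0 / np.pi) * theta - 23.0
            worst_rau = max(worst_rau, abs(gs.rau_transform(correct, total) - expected))

    rng = np.random.default_rng(seed)
    Y = rng.standard_normal((20, 2)) + np.array([0.1, -0.2])
    Y[:10] += 0.3
    groups = np.array(["lvPPA"] * 10 + ["HC"] * 10)
    table = gs.mixed_anova_2x2(Y, groups)

    # independent SS decomposition
    grand = Y.mean()
    subj = Y.mean(axis=1)
    ss_total = ((Y - grand) ** 2).sum()
    ss_bs = 2 * ((subj - grand) ** 2).sum()
    ss_group = 2 * sum(10 * (Y[groups == g].mean() - grand) ** 2 for g in ("lvPPA", "HC"))
    ss_sw = ss_bs - ss_group
    cond = Y.mean(axis=0)
    ss_cond = 20 * ((cond - grand) ** 2).sum()
    ss_int = sum(
        10 * (Y[groups == g, c].mean() - Y[groups == g].mean() - cond[c] + grand) ** 2
        for g in ("lvPPA", "HC")
        for c in (0, 1)
    )
    ss_res = ss_total - ss_bs - ss_cond - ss_int
    oracle_F = {
        "group": ss_group / (ss_sw / 18.0),
        "narrative": ss_cond / (ss_res / 18.0),
        "group:narrative": ss_int / (ss_res / 18.0),
    }
    worst_anova = max(
        abs(table.effects[e]["F"] - oracle_F[e]) for e in oracle_F
    )
    return {"rau_max_abs_err": float(worst_rau), "anova_max_abs_err": float(worst_anova)}
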