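"""Ground-truth synthetic cohorts for end-to-end pipeline testing.

The generator emulates the study conditions: 63 participants, 60 cued-pain
trials each, ratings produced by the precision-weighted rating model with
participant-specific parameters, stimulation-locked multichannel epochs with
a P2-like bump, ROI activity tables with *planted* rank correlations to the
true parameters, and questionnaire covariates generated with no planted
correlation. Because the truth is recorded, every downstream stage —
attention filtering, MCMC recovery, P2 extraction, pruning, hypothesised and
exploratory correlation — can be tested against known answers.

Rank correlations are planted through a Gaussian copula: a target Spearman
rho_s maps to a normal-scores Pearson r = 2 sin(pi * rho_s / 6), so the
sample Spearman correlation converges to rho_s as n grows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .eeg import EpochSet
from .model import ParticipantParams, simulate_ratings
from .task import TaskConfig, simulate_trials, trials_to_frame
from .correlate import ROIRecord, STRUCTURE_CENTROIDS, SENSORY_STRUCTURES, CUE_STRUCTURES

__all__ = [
    "PlantedEffect",
    "ErpSpec",
    "PopulationSpec",
    "CohortBundle",
    "sample_params",
    "plant_rank_correlation",
    "generate_cohort",
    "generate_epochs",
]

COVARIATE_COLUMNS = [
    "mindfulness",
    "attachment_anxiety",
    "attachment_avoidance",
    "catastrophising",
]


@dataclass(frozen=True)
class PlantedEffect:
    """A known rank correlation between a parameter and one ROI's activity."""

    parameter: str  # e.g. "w_stim", "abs_eta", "mu"
    structure: str
    hemisphere: str
    window: str
    rho: float

    def __post_init__(self) -> None:
        if not abs(self.rho) < 1:
            raise ValueError("planted |rho| must be < 1")


@dataclass(frozen=True)
class ErpSpec:
    """Waveform model for synthetic epochs: a P2-like Gaussian bump on one
    channel over 1/f-shaped noise.

    The per-participant bump amplitude is rank-linked (Gaussian copula) to
    ``amp_link_parameter`` with Spearman ``amp_link_rho``, then placed on an
    ``amp_mean`` +/- ``amp_sd`` microvolt scale.
    """

    channels: tuple[str, ...] = (
        "Fz", "Cz", "Pz", "C3", "C4", "F3", "F4", "P3", "P4", "Oz",
    )
    p2_channel: str = "Cz"
    latency_mean_ms: float = 250.0
    latency_sd_ms: float = 30.0
    bump_sd_ms: float = 40.0
    amp_mean: float = 5.0
    amp_sd: float = 1.5
    amp_link_parameter: str = "w_stim"
    amp_link_rho: float = 0.3
    noise_sd: float = 1.0
    srate: float = 500.0
    epoch_start_ms: float = -4500.0
    epoch_end_ms: float = 500.0


@dataclass
class PopulationSpec:
    """Population-level distributions and planted structure of a cohort.

    Defaults mirror the study conditions (63 participants, 60 trials,
    anchors 3/7, 50/50 delivery) with parameter populations chosen so that
    simulated ratings span the 0-100 scale with a low clip rate:
    beta2 ~ logN(log 200, 0.5^2), rho2 ~ logN(log 400, 0.5^2),
    nu2 ~ logN(log 900, 0.5^2), eta ~ N(0, 0.5^2), mu ~ N(50, 15^2).
    """

    n_participants: int = 63
    task: TaskConfig = field(default_factory=TaskConfig)
    beta2_logmean: float = float(np.log(200.0))
    beta2_logsd: float = 0.5
    rho2_logmean: float = float(np.log(400.0))
    rho2_logsd: float = 0.5
    nu2_logmean: float = float(np.log(900.0))
    nu2_logsd: float = 0.5
    eta_mean: float = 0.0
    eta_sd: float = 0.5
    mu_mean: float = 50.0
    mu_sd: float = 15.0
    choice_accuracy: float = 0.95
    planted_effects: tuple[PlantedEffect, ...] = ()
    erp: ErpSpec = field(default_factory=ErpSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 4:
            raise ValueError("need at least 4 participants")
        for name in ("beta2_logsd", "rho2_logsd", "nu2_logsd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.eta_sd < 0 or self.mu_sd < 0:
            raise ValueError("eta_sd and mu_sd must be >= 0")


@dataclass
class CohortBundle:
    """All tables of one synthetic cohort, aligned on participant_id."""

    params_truth: pd.DataFrame
    trials: Optional[pd.DataFrame]
    rois: list[ROIRecord]
    p2: pd.DataFrame
    covariates: pd.DataFrame
    epochs: Optional[list[EpochSet]]
    manifest: dict


def sample_params(pop: PopulationSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Draw the five-parameter truth table for a cohort."""
    n = pop.n_participants
    beta2 = np.exp(rng.normal(pop.beta2_logmean, pop.beta2_logsd, n))
    rho2 = np.exp(rng.normal(pop.rho2_logmean, pop.rho2_logsd, n))
    nu2 = np.exp(rng.normal(pop.nu2_logmean, pop.nu2_logsd, n))
    eta = rng.normal(pop.eta_mean, pop.eta_sd, n)
    mu = rng.normal(pop.mu_mean, pop.mu_sd, n)
    return pd.DataFrame(
        {
            "participant_id": [f"p{i:03d}" for i in range(n)],
            "beta2": beta2,
            "eta": eta,
            "rho2": rho2,
            "mu": mu,
            "nu2": nu2,
            "w_stim": 1.0 / beta2,
            "w_cue": 1.0 / rho2,
            "w_bias": 1.0 / nu2,
        }
    )


def plant_rank_correlation(
    x: np.ndarray, rho_s: float, rng: np.random.Generator
) -> np.ndarray:
    """Generate y with target Spearman correlation to x (Gaussian copula).

    x is converted to normal scores via its mid-ranks; y-scores share
    Pearson correlation r = 2 sin(pi * rho_s / 6) with them and are returned
    on a standard-normal margin.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 observations")
    if not abs(rho_s) < 1:
        raise ValueError("|rho_s| must be < 1")
    if np.ptp(x) == 0:
        raise ValueError("constant x: ranks undefined")
    ranks = stats.rankdata(x, method="average")
    z_x = stats.norm.ppf((ranks - 0.5) / x.size)
    r = 2.0 * np.sin(np.pi * rho_s / 6.0)
    return r * z_x + np.sqrt(1.0 - r**2) * rng.standard_normal(x.size)


def _default_null_rois() -> list[tuple[str, str, str]]:
    """(structure, hemisphere, window) grid for unplanted ROIs."""
    out = []
    structures = sorted(set(SENSORY_STRUCTURES) | set(CUE_STRUCTURES))
    for s in structures:
        for w in ("late_anticipation", "post_stimulation"):
            out.append((s, "R", w))
    return out


def generate_cohort(
    pop: PopulationSpec,
    make_trials: bool = True,
    make_epochs: bool = False,
    roi_layout: Optional[Sequence[tuple[str, str, str]]] = None,
) -> CohortBundle:
    """Build a complete ground-truth cohort.

    Per participant: trials simulated through the task paradigm with
    ratings from the rating model; ROI activities drawn standard-normal
    except where a planted effect ties them to the true parameters; a P2
    table rank-linked to the ERP spec's link parameter; independent
    (null) questionnaire covariates. Epoched waveforms are optional —
    they are bulky and only the EEG-feature stage consumes them.
    """
    root = np.random.SeedSequence(pop.seed)
    ss_params, ss_trials, ss_rois, ss_p2, ss_cov, ss_epochs = root.spawn(6)
    rng = np.random.default_rng(ss_params)
    truth = sample_params(pop, rng)
    n = pop.n_participants

    trials_df = None
    if make_trials:
        frames = []
        clip_rates = []
        for i, child in enumerate(ss_trials.spawn(n)):
            prng = np.random.default_rng(child)
            trials = simulate_trials(pop.task, prng, pop.choice_accuracy)
            params = ParticipantParams(
                beta2=truth.loc[i, "beta2"],
                eta=truth.loc[i, "eta"],
                rho2=truth.loc[i, "rho2"],
                mu=truth.loc[i, "mu"],
                nu2=truth.loc[i, "nu2"],
            )
            X = np.array([t.X for t in trials])
            q = np.array([t.q for t in trials])
            SD = np.array([t.SD for t in trials])
            # aggregate clipping over the cohort; warn once below
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                ratings, _, clip = simulate_ratings(X, q, SD, params, prng)
            clip_rates.append(clip)
            frame = trials_to_frame(trials, truth.loc[i, "participant_id"])
            frame["rating"] = ratings
            frames.append(frame)
        trials_df = pd.concat(frames, ignore_index=True)
        mean_clip = float(np.mean(clip_rates))
        if mean_clip > 0.05:
            warnings.warn(
                f"cohort-average rating clip rate {mean_clip:.1%} exceeds 5%; "
                "population parameters push ratings off the 0-100 scale",
                stacklevel=2,
            )

    # ROI activities: planted effects first, pure noise elsewhere
    roi_rng = np.random.default_rng(ss_rois)
    layout = list(roi_layout) if roi_layout is not None else _default_null_rois()
    planted_keys = {
        (e.structure, e.hemisphere, e.window): e for e in pop.planted_effects
    }
    rois: list[ROIRecord] = []
    for key in planted_keys:
        if key not in layout:
            layout.append(key)
    for structure, hemisphere, window in layout:
        effect = planted_keys.get((structure, hemisphere, window))
        if effect is not None:
            x = _truth_values(truth, effect.parameter)
            activity = plant_rank_correlation(x, effect.rho, roi_rng)
        else:
            activity = roi_rng.standard_normal(n)
        centre = STRUCTURE_CENTROIDS.get(
            (structure, hemisphere), (0.0, 0.0, 0.0)
        )
        mni = tuple(np.asarray(centre) + roi_rng.integers(-6, 7, 3))
        rois.append(
            ROIRecord(
                structure=structure,
                hemisphere=hemisphere,
                mni=mni,
                window=window,
                activity=activity,
            )
        )

    # P2 amplitudes rank-linked to the configured parameter
    p2_rng = np.random.default_rng(ss_p2)
    link = _truth_values(truth, pop.erp.amp_link_parameter)
    z = plant_rank_correlation(link, pop.erp.amp_link_rho, p2_rng)
    amplitude = pop.erp.amp_mean + pop.erp.amp_sd * z
    latency = p2_rng.normal(pop.erp.latency_mean_ms, pop.erp.latency_sd_ms, n)
    latency = np.clip(latency, 120.0, 400.0)
    p2 = pd.DataFrame(
        {
            "participant_id": truth["participant_id"],
            "electrode": pop.erp.p2_channel,
            "latency_ms": latency,
            "amplitude": amplitude,
        }
    )

    cov_rng = np.random.default_rng(ss_cov)
    covariates = pd.DataFrame(
        {
            "participant_id": truth["participant_id"],
            "mindfulness": cov_rng.normal(130.0, 20.0, n),
            "attachment_anxiety": cov_rng.normal(3.5, 1.0, n),
            "attachment_avoidance": cov_rng.normal(3.0, 1.0, n),
            "catastrophising": cov_rng.normal(18.0, 9.0, n),
        }
    )

    epochs = None
    if make_epochs:
        epochs = []
        for i, child in enumerate(ss_epochs.spawn(n)):
            erng = np.random.default_rng(child)
            n_trials = pop.task.n_trials if trials_df is not None else 20
            epochs.append(
                generate_epochs(
                    participant_id=truth.loc[i, "participant_id"],
                    n_trials=n_trials,
                    amplitude=float(amplitude[i]),
                    latency_ms=float(latency[i]),
                    spec=pop.erp,
                    rng=erng,
                )
            )

    manifest = {
        "seed": pop.seed,
        "n_participants": n,
        "planted_effects": [asdict(e) for e in pop.planted_effects],
        "erp": asdict(pop.erp),
        "task": asdict(pop.task),
    }
    return CohortBundle(
        params_truth=truth,
        trials=trials_df,
        rois=rois,
        p2=p2,
        covariates=covariates,
        epochs=epochs,
        manifest=manifest,
    )


def _truth_values(truth: pd.DataFrame, parameter: str) -> np.ndarray:
    if parameter == "abs_eta":
        return np.abs(truth["eta"].to_numpy(dtype=float))
    return truth[parameter].to_numpy(dtype=float)


def _one_over_f_noise(
    n_trials: int, n_ch: int, n_samp: int, sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Spectrally 1/f-shaped Gaussian noise, unit-SD scaled then by ``sd``."""
    white = rng.standard_normal((n_trials, n_ch, n_samp))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samp)
    shaping = np.zeros_like(freqs)
    np.divide(1.0, np.sqrt(freqs), out=shaping, where=freqs > 0)
    shaping[0] = shaping[1] if shaping.size > 1 else 0.0
    shaped = np.fft.irfft(spec * shaping, n=n_samp, axis=-1)
    shaped /= shaped.std()
    return sd * shaped


def generate_epochs(
    participant_id: str,
    n_trials: int,
    amplitude: float,
    latency_ms: float,
    spec: ErpSpec,
    rng: np.random.Generator,
) -> EpochSet:
    """Synthesize stimulation-locked epochs with canonical event markers.

    Markers follow the task's fixed timing: pair onset 4 s before
    stimulation, choice 0.5 s later, cue onset exactly 3 s before
    stimulation (the cue display duration). The P2-like bump sits on
    ``spec.p2_channel`` at the participant's latency; all channels carry
    1/f noise.
    """
    n_samp = int(
        round((spec.epoch_end_ms - spec.epoch_start_ms) * spec.srate / 1000.0)
    )
    t_ms = spec.epoch_start_ms + np.arange(n_samp) * 1000.0 / spec.srate
    stim_idx = int(round(-spec.epoch_start_ms * spec.srate / 1000.0))
    cue_idx = stim_idx - int(round(3000.0 * spec.srate / 1000.0))
    pair_idx = stim_idx - int(round(4000.0 * spec.srate / 1000.0))
    choice_idx = stim_idx - int(round(3500.0 * spec.srate / 1000.0))

    n_ch = len(spec.channels)
    data = _one_over_f_noise(n_trials, n_ch, n_samp, spec.noise_sd, rng)
    bump = amplitude * np.exp(
        -0.5 * ((t_ms - latency_ms) / spec.bump_sd_ms) ** 2
    )
    ch = spec.channels.index(spec.p2_channel)
    data[:, ch, :] += bump[None, :]

    ones = np.full(n_trials, 1, dtype=int)
    events = {
        "pair_onset": pair_idx * ones,
        "choice": choice_idx * ones,
        "cue_onset": cue_idx * ones,
        "stim_onset": stim_idx * ones,
    }
    return EpochSet(
        data=data,
        srate=spec.srate,
        channels=list(spec.channels),
        events=events,
        participant_id=participant_id,
    )
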