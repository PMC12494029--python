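"""Synthetic per-FA force / FAK-activity / area time series.

Single focal adhesions at the leading edge exhibit mechanochemical waves:
the traction-force rate oscillates with a ~5-min period, FAK-activity
changes follow tens of seconds later, and integrated-area growth follows
FAK.  The generator emulates that structure with a latent-factor model on
the *rate* series of each FA,

    R_F(t) = a_F * ( c_F * S(t)              + sqrt(v_F) * e_F(t) )
    R_K(t) = a_K * ( c_K * S(t - tau1)       + sqrt(v_K) * e_K(t) )
    R_A(t) = a_A * ( c_A * S(t - tau1 - tau2) + sqrt(v_A) * e_A(t) )

where S is a shared unit-variance latent oscillation (sinusoid of period P
mixed with a smooth broadband component), e_X are independent smooth unit-
variance noises, v_X are per-channel noise-to-signal variance ratios and
c_X in {0, 1} switch the coupling (perturbation presets).  Under this
model the peak Pearson correlation between two coupled rate channels is

    r_XY = 1 / sqrt((1 + v_X) (1 + v_Y)),

so :func:`calibrate_noise` inverts a target correlation triple in closed
form.  Level series are cumulative integrals of the rates plus a strictly
positive baseline; the analysis pipeline must then recover the embedded
lags, period and correlations through differentiation and z-scoring.

All randomness flows through one seed; a fixed seed reproduces identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from ..dynamics import TRACE_COLUMNS

#: Correlation triple and lag chain reported for untreated (DMSO) cells:
#: force-area r = 0.67, force-FAK r = 0.61, FAK-area r = 0.49;
#: force leads FAK by 32 s, FAK leads area by ~21 s; latent period ~5 min.
PAPER_CORRELATIONS = {"force_area": 0.67, "force_fak": 0.61, "fak_area": 0.49}
PAPER_LAG_FORCE_FAK_S = 32.0
PAPER_LAG_FAK_AREA_S = 21.0
PAPER_PERIOD_S = 300.0


class InfeasibleCorrelationError(ValueError):
    """Raised when a correlation triple admits no nonnegative noise ratios."""


def calibrate_noise(
    target_r_force_area: float,
    target_r_force_fak: float,
    target_r_fak_area: float,
) -> tuple[float, float, float]:
    """Noise-to-signal variance ratios (vF, vK, vA) reproducing a target
    pairwise correlation triple under the latent-factor model.

    With r_XY = 1/sqrt((1+vX)(1+vY)) the unique solution is

        1 + vF = r_KA / (r_FK * r_FA),   and cyclically,

    where F/K/A index force, FAK and area.  Raises
    :class:`InfeasibleCorrelationError` when any implied variance ratio is
    negative (the product of two targets exceeding the third).
    """
    r_fa, r_fk, r_ka = target_r_force_area, target_r_force_fak, target_r_fak_area
    for name, r in (("force_area", r_fa), ("force_fak", r_fk), ("fak_area", r_ka)):
        if not 0 < r <= 1:
            raise ValueError(f"target correlation {name} must be in (0, 1], got {r}")
    v_f = r_ka / (r_fk * r_fa) - 1.0
    v_k = r_fa / (r_fk * r_ka) - 1.0
    v_a = r_fk / (r_fa * r_ka) - 1.0
    if min(v_f, v_k, v_a) < 0:
        raise InfeasibleCorrelationError(
            f"correlation triple (r_FA={r_fa}, r_FK={r_fk}, r_KA={r_ka}) is "
            f"infeasible: implied variance ratios ({v_f:.3g}, {v_k:.3g}, "
            f"{v_a:.3g}) are not all nonnegative"
        )
    return float(v_f), float(v_k), float(v_a)


@dataclass(frozen=True)
class TraceGenConfig:
    """Configuration of the per-FA trace generator.

    Times are seconds; forces nN; areas um^2; the FAK channel is the
    dimensionless donor/cFRET ratio.  ``noise_ratios`` are the per-channel
    independent-noise-to-latent-signal variance ratios (vF, vK, vA);
    ``coupling`` switches each channel's latent drive on/off (perturbation
    presets set entries to 0).  ``sinusoid_weight`` is the variance
    fraction of the latent carried by the pure sinusoid (the rest is a
    smooth broadband component with Gaussian correlation
    ``smooth_sigma_s``).
    """

    n_fas: int = 100
    n_cells: int = 1
    duration_s: float = 1200.0
    frame_interval_s: float = 10.0
    period_s: float = PAPER_PERIOD_S
    lag_tau1_s: float = PAPER_LAG_FORCE_FAK_S
    lag_tau2_s: float = PAPER_LAG_FAK_AREA_S
    noise_ratios: tuple[float, float, float] = calibrate_noise(
        PAPER_CORRELATIONS["force_area"],
        PAPER_CORRELATIONS["force_fak"],
        PAPER_CORRELATIONS["fak_area"],
    )
    coupling: tuple[float, float, float] = (1.0, 1.0, 1.0)
    rate_amplitudes: tuple[float, float, float] = (0.5, 0.05, 0.3)
    baselines: tuple[float, float, float] = (2.0, 1.4, 2.0)
    sinusoid_weight: float = 0.7
    smooth_sigma_s: float = 15.0
    preset: str = "custom"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be > 0")
        if self.duration_s < 7 * self.frame_interval_s:
            raise ValueError("duration_s must cover at least 7 frames")
        if any(v < 0 for v in self.noise_ratios):
            raise ValueError("noise_ratios must be >= 0")
        if self.period_s <= 2 * self.frame_interval_s:
            raise ValueError("period_s must exceed 2 frame intervals (Nyquist)")
        if not 0 <= self.sinusoid_weight <= 1:
            raise ValueError("sinusoid_weight must be in [0, 1]")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s / self.frame_interval_s)) + 1


def trace_preset(name: str, **overrides) -> TraceGenConfig:
    """Named generator presets.

    ``paper_default``
        Untreated (DMSO) conditions: 5-min latent period, force leads FAK
        by 32 s, FAK leads area by 21 s, noise calibrated to the
        0.67/0.61/0.49 correlation triple.
    ``rock_inhibited``
        Contractility inhibition (Y-27632): latent amplitude 0 for every
        channel, force held at a low baseline with only small independent
        noise — no oscillation, no coupling, no force growth.
    ``fak_inhibited``
        FAK inhibition (PF-573228): the FAK channel is decoupled from the
        latent wave and its baseline drops to 0.8, while force (and its
        coupling to area) persists.
    """
    presets: dict[str, dict] = {
        "paper_default": {},
        "rock_inhibited": {
            "coupling": (0.0, 0.0, 0.0),
            "rate_amplitudes": (0.01, 0.01, 0.3),
            "baselines": (0.5, 1.4, 2.0),
        },
        "fak_inhibited": {
            "coupling": (1.0, 0.0, 1.0),
            "baselines": (2.0, 0.8, 2.0),
        },
    }
    if name not in presets:
        raise KeyError(f"unknown trace preset {name!r}; choose from {sorted(presets)}")
    kwargs = {**presets[name], **overrides}
    return TraceGenConfig(preset=name, **kwargs)


@dataclass
class TraceGroundTruth:
    """Generator-side truth for one trace ensemble."""

    period_s: float
    lag_force_fak_s: float
    lag_fak_area_s: float
    lag_force_area_s: float
    noise_ratios: tuple[float, float, float]
    target_correlations: dict[str, float]
    coupling: tuple[float, float, float]
    true_rates: dict[str, np.ndarray] = field(repr=False)  # (n_fas, T) per channel
    phases: np.ndarray = field(repr=False)

    def to_jsonable(self) -> dict:
        return {
            "period_s": self.period_s,
            "lag_force_fak_s": self.lag_force_fak_s,
            "lag_fak_area_s": self.lag_fak_area_s,
            "lag_force_area_s": self.lag_force_area_s,
            "noise_ratios": list(self.noise_ratios),
            "target_correlations": self.target_correlations,
            "coupling": list(self.coupling),
            "phases": self.phases.tolist(),
        }


def _smooth_unit_noise(
    rng: np.random.Generator, n: int, sigma_samples: float
) -> np.ndarray:
    """Unit-variance smooth noise: Gaussian-filtered white noise with the
    filtered edges trimmed away."""
    pad = int(np.ceil(4 * sigma_samples))
    x = gaussian_filter1d(rng.standard_normal(n + 2 * pad), sigma_samples)
    x = x[pad : pad + n]
    sd = x.std()
    return x / sd if sd > 0 else x


_FINE_DT_S = 1.0  # latent sampled on a 1-s grid so lags land exactly


def generate_traces(config: TraceGenConfig) -> tuple[pd.DataFrame, TraceGroundTruth]:
    """Generate a per-FA trace table plus ground truth.

    Returns a tidy DataFrame with columns ``cell_id, fa_id, frame, time_s,
    force_nN, fak_ratio, area_um2`` and a :class:`TraceGroundTruth`
    recording the embedded lags, period, correlation targets and the exact
    rate series from which the levels were integrated.
    """
    rng = np.random.default_rng(config.seed)
    dt = config.frame_interval_s
    n_frames = config.n_frames
    tau1, tau2 = config.lag_tau1_s, config.lag_tau2_s
    max_shift = tau1 + tau2
    # fine time grid extended into negative time to cover the shifts
    n_pre = int(np.ceil(max_shift / _FINE_DT_S))
    t_fine = np.arange(-n_pre, int(round(config.duration_s / _FINE_DT_S)) + 1) * _FINE_DT_S
    frame_times = np.arange(n_frames) * dt
    frame_idx = np.rint((frame_times - t_fine[0]) / _FINE_DT_S).astype(int)
    sig_fine = config.smooth_sigma_s / _FINE_DT_S

    w = config.sinusoid_weight
    vF, vK, vA = config.noise_ratios
    cF, cK, cA = config.coupling
    aF, aK, aA = config.rate_amplitudes
    bF, bK, bA = config.baselines

    def sample_shifted(series: np.ndarray, shift_s: float) -> np.ndarray:
        idx = frame_idx - int(round(shift_s / _FINE_DT_S))
        return series[idx]

    phases = rng.uniform(0, 2 * np.pi, config.n_fas)
    rates = {
        "force_nN": np.empty((config.n_fas, n_frames)),
        "fak_ratio": np.empty((config.n_fas, n_frames)),
        "area_um2": np.empty((config.n_fas, n_frames)),
    }
    rows = []
    fas_per_cell = int(np.ceil(config.n_fas / config.n_cells))
    for i in range(config.n_fas):
        sinus = np.sqrt(2.0) * np.sin(2 * np.pi * t_fine / config.period_s + phases[i])
        broad = _smooth_unit_noise(rng, t_fine.size, sig_fine)
        latent = np.sqrt(w) * sinus + np.sqrt(1 - w) * broad
        eps = [
            _smooth_unit_noise(rng, t_fine.size, sig_fine) for _ in range(3)
        ]
        r_f = aF * (cF * sample_shifted(latent, 0.0) + np.sqrt(vF) * sample_shifted(eps[0], 0.0))
        r_k = aK * (cK * sample_shifted(latent, tau1) + np.sqrt(vK) * sample_shifted(eps[1], 0.0))
        r_a = aA * (cA * sample_shifted(latent, tau1 + tau2) + np.sqrt(vA) * sample_shifted(eps[2], 0.0))
        rates["force_nN"][i] = r_f
        rates["fak_ratio"][i] = r_k
        rates["area_um2"][i] = r_a

        dt_min = dt / 60.0  # rates are per-minute
        levels = {
            "force_nN": bF + _cumtrapz(r_f, dt_min),
            "fak_ratio": bK + _cumtrapz(r_k, dt_min),
            "area_um2": bA + _cumtrapz(r_a, dt_min),
        }
        cell = f"cell{i // fas_per_cell:02d}"
        for j in range(n_frames):
            rows.append(
                (cell, f"fa{i:03d}", j, frame_times[j],
                 levels["force_nN"][j], levels["fak_ratio"][j], levels["area_um2"][j])
            )
    df = pd.DataFrame(rows, columns=TRACE_COLUMNS)
    truth = TraceGroundTruth(
        period_s=config.period_s,
        lag_force_fak_s=tau1,
        lag_fak_area_s=tau2,
        lag_force_area_s=tau1 + tau2,
        noise_ratios=config.noise_ratios,
        target_correlations={
            "force_fak": 1.0 / np.sqrt((1 + vF) * (1 + vK)),
            "fak_area": 1.0 / np.sqrt((1 + vK) * (1 + vA)),
            "force_area": 1.0 / np.sqrt((1 + vF) * (1 + vA)),
        },
        coupling=config.coupling,
        true_rates=rates,
        phases=phases,
    )
    return df, truth


def _cumtrapz(rate: np.ndarray, dx: float) -> np.ndarray:
    out = np.empty_like(rate)
    out[0] = 0.0
    np.cumsum((rate[1:] + rate[:-1]) * 0.5 * dx, out=out[1:])
    return out


def monte_carlo_pair_correlations(
    config: TraceGenConfig, n_samples: int = 100_000, seed: int = 1
) -> dict[str, float]:
    """Independent Monte-Carlo check of the calibration algebra: draw
    latent and noise as plain i.i.d. normals (no time structure) and return
    the empirical Pearson correlations of the three channel pairs."""
    rng = np.random.default_rng(seed)
    vF, vK, vA = config.noise_ratios
    s = rng.standard_normal(n_samples)
    f = s + np.sqrt(vF) * rng.standard_normal(n_samples)
    k = s + np.sqrt(vK) * rng.standard_normal(n_samples)
    a = s + np.sqrt(vA) * rng.standard_normal(n_samples)
    def r(x, y):
        return float(np.corrcoef(x, y)[0, 1])
    return {"force_fak": r(f, k), "fak_area": r(k, a), "force_area": r(f, a)}
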