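"""Synthetic continuous recordings with known ground truth.

Event trains with normally distributed inter-event intervals are
convolved with fixed response kernels (boxcar, Dirac, parametric ERP,
pink noise); per-event covariates modulate component amplitudes linearly
or logarithmically, correlated covariate pairs are built through a
Gaussian copula, and Gaussian white noise is added on top.  Every
scenario returns the exact noiseless kernels and per-event responses, so
recovery error is computable without re-derivation.

Presets encode the package's standard validation scenarios:

``fig10_boxcar`` / ``fig10_dirac`` / ``fig10_erp`` / ``fig10_pink``
    5 s of data, inter-event intervals ~ normal(0.25 s, 0.05 s), one
    kernel shape each — heavy overlap, intercept-only model.
``fig7``
    38 events, one effective covariate plus a null covariate correlated
    at r = 0.85, Gaussian noise SD 1 — the regularization scenario.
``fig1``
    a two-condition stimulus-discrimination task with condition-
    dependent response times (button-press overlap) and a logarithmic
    luminance effect on the P1 — the spurious-difference demonstration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "Kernel",
    "ResponseComponent",
    "CovariateSpec",
    "EventTypeSpec",
    "TrialSpec",
    "SimScenario",
    "make_kernel",
    "draw_events",
    "render_continuous",
    "simulate",
    "preset",
    "PRESET_NAMES",
]

MIN_GAP_SAMPLES = 2  # truncation floor for inter-event intervals


@dataclass
class Kernel:
    """A fixed response shape sampled over a causal window."""

    name: str
    samples: np.ndarray
    srate: float
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("kernel samples must be finite")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def duration(self) -> float:
        return (self.n_samples - 1) / self.srate


def _gauss(t, amp, lat, width):
    return amp * np.exp(-0.5 * ((t - lat) / width) ** 2)


def make_kernel(
    name: str, srate: float, duration: float = 0.6, seed: Optional[int] = None,
    **params,
) -> Kernel:
    """Construct one of the standard response shapes.

    ``duration`` is the causal kernel window in seconds; the sample
    vector has ``round(duration*srate) + 1`` entries so it aligns with
    an inclusive model window ``[0, duration]``.

    boxcar
        1 on ``[t_on, t_off)`` (defaults 0.1–0.4 s), else 0.
    dirac
        a single unit sample at ``latency`` (default 0.2 s).
    auditory_erp
        sum of three Gaussian components (positive P1, negative N1,
        positive P2); amplitudes/latencies/widths configurable.
    pinknoise
        seeded 1/f-shaped noise, normalized to unit peak amplitude.
    """
    n = int(np.rint(duration * srate)) + 1
    t = np.arange(n) / srate
    if name == "boxcar":
        t_on = params.get("t_on", 0.1)
        t_off = params.get("t_off", 0.4)
        if not 0 <= t_on < t_off:
            raise ValueError("boxcar needs 0 <= t_on < t_off")
        samples = ((t >= t_on) & (t < t_off)).astype(float)
    elif name == "dirac":
        latency = params.get("latency", 0.2)
        idx = int(np.rint(latency * srate))
        if not 0 <= idx < n:
            raise ValueError("dirac latency outside the kernel window")
        samples = np.zeros(n)
        samples[idx] = 1.0
    elif name == "auditory_erp":
        comps = params.get(
            "components",
            [  # (amplitude, latency s, width s): P1, N1, P2
                (1.2, 0.08, 0.02),
                (-2.0, 0.15, 0.03),
                (1.0, 0.30, 0.06),
            ],
        )
        samples = np.zeros(n)
        for amp, lat, width in comps:
            samples += _gauss(t, amp, lat, width)
    elif name == "pinknoise":
        if seed is None:
            raise ValueError("pinknoise kernel requires a seed")
        rng = np.random.default_rng(seed)
        white = rng.standard_normal(n)
        spec = np.fft.rfft(white)
        freqs = np.fft.rfftfreq(n, d=1.0 / srate)
        shaping = np.ones_like(freqs)
        shaping[1:] = 1.0 / np.sqrt(freqs[1:])  # power ~ 1/f
        shaping[0] = 0.0  # no DC
        samples = np.fft.irfft(spec * shaping, n=n)
        samples = samples / np.max(np.abs(samples))
    elif name == "custom":
        samples = np.asarray(params["samples"], dtype=float)
    else:
        raise ValueError(f"unknown kernel {name!r}")
    return Kernel(name, samples, srate, {**params, "duration": duration, "seed": seed})


@dataclass
class ResponseComponent:
    """One additive component of an event type's response.

    The contribution of event ``i`` is ``gain_i * kernel`` with

    - ``const``:      gain = scale
    - ``linear``:     gain = scale * x_i
    - ``log``:        gain = scale * log(x_i)
    - ``indicator``:  gain = scale * (x_i == level)
    """

    kernel: Kernel
    gain: str = "const"
    covariate: Optional[str] = None
    scale: float = 1.0
    level: Optional[str] = None

    def gains(self, events: pd.DataFrame) -> np.ndarray:
        n = len(events)
        if self.gain == "const":
            return np.full(n, self.scale)
        x = events[self.covariate]
        if self.gain == "linear":
            return self.scale * x.to_numpy(dtype=float)
        if self.gain == "log":
            vals = x.to_numpy(dtype=float)
            if np.any(vals <= 0):
                raise ValueError("log gain needs strictly positive covariate")
            return self.scale * np.log(vals)
        if self.gain == "indicator":
            return self.scale * (x.astype(str) == self.level).to_numpy(float)
        raise ValueError(f"unknown gain {self.gain!r}")


@dataclass
class CovariateSpec:
    """Marginal distribution (and optional correlation) of a covariate.

    ``dist`` forms: ``("uniform", lo, hi)``, ``("normal", mu, sd)``,
    ``("choice", [levels...])`` and
    ``("normal_by_level", other, {level: (mu, sd)})``.  ``corr_with``
    ties a continuous covariate to an earlier one through a Gaussian
    copula targeting Pearson correlation ``corr``.
    """

    name: str
    dist: tuple = ("uniform", 0.0, 1.0)
    corr_with: Optional[str] = None
    corr: float = 0.0


@dataclass
class EventTypeSpec:
    components: list[ResponseComponent]
    isi_mean: float = 0.25
    isi_sd: float = 0.05
    n_events: Optional[int] = None
    covariates: list[CovariateSpec] = field(default_factory=list)


@dataclass
class TrialSpec:
    """Stimulus–response linkage: one response event per stimulus.

    Response onset = stimulus onset + a reaction time drawn from the
    per-level normal distribution ``rt[level]`` (mean, sd in seconds),
    floored at ``min_rt``.
    """

    stimulus: str
    response: str
    condition: str
    rt: dict[str, tuple[float, float]]
    min_rt: float = 0.05


@dataclass
class SimScenario:
    srate: float
    event_types: dict[str, EventTypeSpec]
    duration: Optional[float] = None  # None: derive from events + kernels
    noise_sd: float = 0.0
    trial: Optional[TrialSpec] = None
    name: str = ""

    def __post_init__(self):
        for etype, spec in self.event_types.items():
            if spec.isi_mean <= 0:
                raise ValueError(f"ISI mean must be positive ({etype})")
            if spec.isi_sd < 0:
                raise ValueError(f"ISI sd must be non-negative ({etype})")


# ---------------------------------------------------------------------------
# event generation
# ---------------------------------------------------------------------------


def _draw_train(spec: EventTypeSpec, srate, duration, rng) -> np.ndarray:
    """Cumulative sum of truncated-normal inter-event intervals."""
    min_gap = MIN_GAP_SAMPLES / srate
    if spec.isi_mean <= min_gap and spec.isi_sd == 0:
        raise ValueError("ISI mean below the truncation floor")
    onsets = []
    t = 0.0
    limit = spec.n_events if spec.n_events is not None else math.inf
    while len(onsets) < limit:
        isi = max(rng.normal(spec.isi_mean, spec.isi_sd), min_gap)
        t += isi
        if duration is not None and t >= duration:
            break
        onsets.append(t)
        if duration is None and spec.n_events is None:
            raise ValueError("need either duration or n_events")
    return np.asarray(onsets)


def _draw_covariates(
    specs: list[CovariateSpec], n: int, rng
) -> dict[str, np.ndarray]:
    values: dict[str, np.ndarray] = {}
    latent: dict[str, np.ndarray] = {}
    for cov in specs:
        kind = cov.dist[0]
        if kind == "choice":
            values[cov.name] = rng.choice(np.asarray(cov.dist[1]), size=n)
            continue
        if kind == "normal_by_level":
            other, table = cov.dist[1], cov.dist[2]
            base = values[other].astype(str)
            out = np.empty(n)
            for level, (mu, sd) in table.items():
                mask = base == str(level)
                out[mask] = rng.normal(mu, sd, size=int(mask.sum()))
            values[cov.name] = out
            continue
        # continuous marginals through a Gaussian copula
        z = rng.standard_normal(n)
        if cov.corr_with is not None:
            if cov.corr_with not in latent:
                raise ValueError(
                    f"covariate {cov.name!r} correlates with "
                    f"{cov.corr_with!r}, which has no Gaussian latent"
                )
            r = cov.corr
            z = r * latent[cov.corr_with] + np.sqrt(1 - r**2) * z
        latent[cov.name] = z
        if kind == "uniform":
            lo, hi = cov.dist[1], cov.dist[2]
            values[cov.name] = lo + (hi - lo) * norm.cdf(z)
        elif kind == "normal":
            mu, sd = cov.dist[1], cov.dist[2]
            values[cov.name] = mu + sd * z
        else:
            raise ValueError(f"unknown distribution {kind!r}")
    return values


def draw_events(scenario: SimScenario, seed: int) -> pd.DataFrame:
    """Draw the event table (onsets, types, covariates) for a scenario."""
    rng = np.random.default_rng(seed)
    frames = []
    trial = scenario.trial
    for etype, spec in scenario.event_types.items():
        if trial is not None and etype == trial.response:
            continue  # generated from the stimulus train below
        onsets = _draw_train(spec, scenario.srate, scenario.duration, rng)
        frame = pd.DataFrame({"onset": onsets, "type": etype})
        for name, vals in _draw_covariates(spec.covariates, len(frame), rng).items():
            frame[name] = vals
        frames.append(frame)
        if trial is not None and etype == trial.stimulus:
            levels = frame[trial.condition].astype(str)
            rts = np.empty(len(frame))
            for level, (mu, sd) in trial.rt.items():
                mask = (levels == str(level)).to_numpy()
                rts[mask] = rng.normal(mu, sd, size=int(mask.sum()))
            rts = np.maximum(rts, trial.min_rt)
            frames.append(
                pd.DataFrame(
                    {"onset": frame["onset"] + rts, "type": trial.response}
                )
            )
    events = pd.concat(frames, ignore_index=True)
    events = events.sort_values("onset", kind="stable").reset_index(drop=True)
    events["orig_index"] = np.arange(len(events))
    if scenario.duration is not None:
        events = events[events["onset"] < scenario.duration].reset_index(drop=True)
    return events


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _scenario_n_samples(scenario: SimScenario, events: pd.DataFrame) -> int:
    if scenario.duration is not None:
        return int(np.rint(scenario.duration * scenario.srate))
    last = 0.0
    for etype, spec in scenario.event_types.items():
        sub = events[events["type"] == etype]
        if len(sub):
            kmax = max(c.kernel.duration for c in spec.components)
            last = max(last, sub["onset"].max() + kmax)
    return int(np.ceil(last * scenario.srate)) + 1


def render_continuous(
    events: pd.DataFrame,
    scenario: SimScenario,
    seed: int,
    n_channels: int = 1,
):
    """Superpose per-event responses and add Gaussian noise.

    ``y(t) = sum_i gain_i * kernel(t - onset_i) + noise`` — overlapping
    responses add linearly by construction.  Returns ``(data, truth)``
    where ``data`` is channels × samples and ``truth`` holds, per event
    type, the noiseless per-event responses, the per-component kernels
    and the constant (intercept) kernel.
    """
    rng = np.random.default_rng(seed)
    n = _scenario_n_samples(scenario, events)
    clean = np.zeros(n)
    truth: dict[str, dict] = {}
    for etype, spec in scenario.event_types.items():
        sub = events[events["type"] == etype]
        onsets = np.rint(sub["onset"].to_numpy(dtype=float) * scenario.srate).astype(
            int
        )
        n_k = max(c.kernel.n_samples for c in spec.components)
        responses = np.zeros((len(sub), n_k))
        for comp in spec.components:
            gains = comp.gains(sub)
            responses[:, : comp.kernel.n_samples] += (
                gains[:, None] * comp.kernel.samples[None, :]
            )
        for onset, resp in zip(onsets, responses):
            stop = min(onset + n_k, n)
            if stop > onset >= 0:
                clean[onset:stop] += resp[: stop - onset]
        intercept = np.zeros(n_k)
        for comp in spec.components:
            if comp.gain == "const":
                intercept[: comp.kernel.n_samples] += comp.scale * comp.kernel.samples
        truth[etype] = {
            "responses": responses,
            "onset_samples": onsets,
            "components": list(spec.components),
            "intercept_kernel": intercept,
            "kernel_duration": (n_k - 1) / scenario.srate,
        }
    data = np.tile(clean, (n_channels, 1))
    if scenario.noise_sd > 0:
        data = data + rng.normal(0.0, scenario.noise_sd, size=data.shape)
    return data, truth


def simulate(scenario: SimScenario, seed: int, n_channels: int = 1):
    """Draw events and render the recording; returns (data, events, truth).

    Determinism: identical scenario + seed give bitwise-identical
    outputs.  Events and noise use independent streams derived from
    ``seed``.
    """
    events = draw_events(scenario, seed)
    data, truth = render_continuous(
        events, scenario, seed=seed + 1, n_channels=n_channels
    )
    return data, events, truth


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

PRESET_NAMES = (
    "fig1",
    "fig7",
    "fig10_boxcar",
    "fig10_dirac",
    "fig10_erp",
    "fig10_pink",
)

_PINK_SEED = 20231115  # fixed: the pink-noise kernel is a known ground truth


def preset(name: str) -> SimScenario:
    """A fully parameterized standard scenario (see module docstring)."""
    srate = 100.0
    if name.startswith("fig10_"):
        shape = name.split("_", 1)[1]
        kernel_name = {
            "boxcar": "boxcar",
            "dirac": "dirac",
            "erp": "auditory_erp",
            "pink": "pinknoise",
        }.get(shape)
        if kernel_name is None:
            raise ValueError(f"unknown preset {name!r}")
        kernel = make_kernel(
            kernel_name,
            srate,
            duration=0.6,
            seed=_PINK_SEED if kernel_name == "pinknoise" else None,
        )
        return SimScenario(
            srate=srate,
            duration=5.0,
            event_types={
                "stim": EventTypeSpec(
                    components=[ResponseComponent(kernel)],
                    isi_mean=0.25,
                    isi_sd=0.05,
                )
            },
            noise_sd=0.0,
            name=name,
        )
    if name == "fig7":
        kernel = make_kernel("auditory_erp", srate, duration=0.6)
        return SimScenario(
            srate=srate,
            duration=None,
            event_types={
                "stim": EventTypeSpec(
                    components=[
                        ResponseComponent(kernel),
                        ResponseComponent(
                            kernel, gain="linear", covariate="covariate", scale=0.5
                        ),
                    ],
                    isi_mean=0.25,
                    isi_sd=0.05,
                    n_events=38,
                    covariates=[
                        CovariateSpec("covariate", ("normal", 0.0, 1.0)),
                        CovariateSpec(
                            "random_covariate",
                            ("normal", 0.0, 1.0),
                            corr_with="covariate",
                            corr=0.85,
                        ),
                    ],
                )
            },
            noise_sd=1.0,
            name=name,
        )
    if name == "fig1":
        p1 = make_kernel(
            "auditory_erp", srate, duration=0.6, components=[(1.0, 0.10, 0.025)]
        )
        n170 = make_kernel(
            "auditory_erp", srate, duration=0.6, components=[(-1.0, 0.17, 0.03)]
        )
        p3 = make_kernel(
            "auditory_erp", srate, duration=0.6, components=[(0.8, 0.35, 0.08)]
        )
        motor = make_kernel(
            "auditory_erp",
            srate,
            duration=0.6,
            components=[(-0.6, 0.05, 0.04), (1.2, 0.18, 0.05)],
        )
        stim = EventTypeSpec(
            components=[
                ResponseComponent(p1, scale=1.5),  # baseline P1
                ResponseComponent(p1, gain="log", covariate="luminance", scale=0.4),
                ResponseComponent(n170, scale=1.0),  # baseline N170
                ResponseComponent(
                    n170, gain="indicator", covariate="is_face",
                    level="face", scale=1.0,  # faces: larger (more negative) N170
                ),
                ResponseComponent(p3, scale=1.0),
            ],
            isi_mean=1.2,
            isi_sd=0.2,
            n_events=60,
            covariates=[
                CovariateSpec("is_face", ("choice", ["face", "house"])),
                CovariateSpec(
                    "luminance",
                    (
                        "normal_by_level",
                        "is_face",
                        {"face": (14.0, 2.0), "house": (10.0, 2.0)},
                    ),
                ),
            ],
        )
        button = EventTypeSpec(components=[ResponseComponent(motor)], isi_mean=1.2)
        return SimScenario(
            srate=srate,
            duration=None,
            event_types={"stim": stim, "button": button},
            noise_sd=0.0,
            trial=TrialSpec(
                stimulus="stim",
                response="button",
                condition="is_face",
                rt={"face": (0.38, 0.06), "house": (0.52, 0.07)},
            ),
            name=name,
        )
    raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
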