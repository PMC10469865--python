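"""Synthetic labeled EEG with planted hemispheric asymmetries.

Each channel is a sum of spectrally confined stochastic components: five
band-limited oscillations on the dyadic analysis intervals, plus 1/f^a
broadband background split into a below-delta and an above-gamma part.
An asymmetry effect for (emotion, band, pairs) is planted so that the
*measured* mean log-ratio of relative wavelet band energies (after the
standard preprocessing chain) equals the requested ``log_effect``:
the target band's content is boosted on the left and attenuated on the
right in a symmetric +/- log_effect/2 energy split, with gains corrected
for the spectral leakage of the short db2 filter bank and for the
band-pass filter, and with the out-of-band background absorbing the
energy difference so left/right totals stay identical.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field, asdict

import numpy as np

from . import dwt
from .features import BANDS, BAND_EDGES, BAND_LEVELS
from .montage import DEFAULT_MONTAGE, PAIRED_CHANNELS, build_pair_map
from .preprocess import bandpass_magnitude_response
from .recording import EEGRecording, EMOTIONS

#: Spectral intervals used by the generator: the five analysis bands plus
#: the out-of-band background reservoirs.
INTERVALS: tuple[str, ...] = ("low",) + BANDS + ("high",)
INTERVAL_EDGES: dict[str, tuple[float, float]] = {
    "low": (0.5, 1.5625),
    **BAND_EDGES,
    "high": (50.0, 100.0),
}
_SEG_SAMPLES = 800
_SEG_FS = 200.0

DEFAULT_BAND_PROFILES: dict[str, float] = {
    "delta": 2.0, "theta": 1.5, "alpha": 1.5, "beta": 1.2, "gamma": 1.0,
}


@dataclass(frozen=True)
class AsymmetryEffect:
    """Planted ground-truth asymmetry for one (emotion, band) cell.

    ``pairs`` is "all" or a collection of 1-based pair indices from the
    canonical 27-pair map. ``log_effect`` is the target mean of
    log(E_left / E_right) over segments of the given emotion.
    """

    emotion: str
    band: str
    log_effect: float
    pairs: object = "all"

    def __post_init__(self) -> None:
        if self.band not in BANDS:
            raise ValueError(f"unknown band {self.band!r}; expected one of {BANDS}")
        if self.emotion not in EMOTIONS:
            raise ValueError(f"unknown emotion {self.emotion!r}")
        if not np.isfinite(self.log_effect):
            raise ValueError("log_effect must be finite")

    def pair_indices(self) -> tuple[int, ...]:
        if isinstance(self.pairs, str):
            if self.pairs != "all":
                raise ValueError(f"pairs must be 'all' or indices, got {self.pairs!r}")
            return tuple(range(1, len(PAIRED_CHANNELS) + 1))
        idx = tuple(int(p) for p in self.pairs)
        for p in idx:
            if not 1 <= p <= len(PAIRED_CHANNELS):
                raise ValueError(f"pair index {p} out of range 1..27")
        return idx


@dataclass
class GeneratorSpec:
    """Full description of one synthetic dataset."""

    n_subjects: int = 15
    n_sessions: int = 3
    trials_per_session_per_emotion: int = 6
    trial_duration: float = 120.0
    fs: float = 200.0
    montage: tuple[str, ...] = DEFAULT_MONTAGE
    emotions: tuple[str, ...] = EMOTIONS
    band_profiles: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BAND_PROFILES)
    )
    noise_weight: float = 3.0
    asymmetry_effects: tuple[AsymmetryEffect, ...] = ()
    subject_sd: float = 0.15
    noise_exponent: float = 1.0
    rms: float = 30.0
    bandpass: tuple[float, float] | None = (0.5, 50.0)
    seed: int = 0

    def __post_init__(self) -> None:
        self.montage = tuple(str(c).upper() for c in self.montage)
        self.emotions = tuple(self.emotions)
        self.asymmetry_effects = tuple(
            e if isinstance(e, AsymmetryEffect) else AsymmetryEffect(**e)
            for e in self.asymmetry_effects
        )
        self.validate()

    def validate(self) -> None:
        for name in ("n_subjects", "n_sessions", "trials_per_session_per_emotion"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        n = self.trial_duration * self.fs
        if abs(n - round(n)) > 1e-9:
            raise ValueError("trial_duration * fs must be an integer sample count")
        if any(w <= 0 for w in self.band_profiles.values()):
            raise ValueError("band_profiles weights must be positive")
        if set(self.band_profiles) != set(BANDS):
            raise ValueError(f"band_profiles must cover exactly the bands {BANDS}")
        if self.noise_weight <= 0:
            raise ValueError("noise_weight must be positive")
        build_pair_map(self.montage)  # raises listing missing lateral labels
        counts = {ch: 0 for ch in self.montage}
        for pair in PAIRED_CHANNELS:
            for ch in pair:
                counts[ch] += 1
        if any(v > 1 for v in counts.values()):
            raise ValueError("montage repeats a paired label")
        if set(self.emotions) - set(EMOTIONS):
            raise ValueError(f"emotions must be drawn from {EMOTIONS}")

    @property
    def n_trial_samples(self) -> int:
        return int(round(self.trial_duration * self.fs))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["montage"] = list(self.montage)
        d["emotions"] = list(self.emotions)
        d["asymmetry_effects"] = [asdict(e) for e in self.asymmetry_effects]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorSpec":
        d = dict(d)
        if "bandpass" in d and d["bandpass"] is not None:
            d["bandpass"] = tuple(d["bandpass"])
        return cls(**d)


def seed_iv_spec(**overrides) -> GeneratorSpec:
    """SEED-IV analogue: 15 subjects x 3 sessions x 24 trials (6 per emotion)."""
    base = dict(n_subjects=15, n_sessions=3, trials_per_session_per_emotion=6,
                trial_duration=120.0)
    base.update(overrides)
    return GeneratorSpec(**base)


def seed_v_spec(**overrides) -> GeneratorSpec:
    """SEED-V analogue (disgust excluded): 16 subjects x 3 sessions x 12 trials."""
    base = dict(n_subjects=16, n_sessions=3, trials_per_session_per_emotion=3,
                trial_duration=120.0)
    base.update(overrides)
    return GeneratorSpec(**base)


# ---------------------------------------------------------------------------
# band-limited component primitive

def generate_band_limited_component(
    band: str, rms: float, duration: float, fs: float, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian waveform spectrally confined to one analysis band.

    All spectral power lies inside the band's dyadic interval and the sample
    RMS equals ``rms`` exactly (zero rms yields the all-zero waveform).
    """
    if band not in BAND_EDGES:
        raise ValueError(f"unknown band {band!r}; expected one of {BANDS}")
    n = int(round(duration * fs))
    if abs(duration * fs - n) > 1e-9:
        raise ValueError("duration * fs must be an integer sample count")
    lo, hi = BAND_EDGES[band]
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    mask = (freqs >= lo) & (freqs < hi)
    if not mask.any():
        raise ValueError(f"no spectral bins inside {band} for duration {duration}s")
    spec = np.zeros(len(freqs), dtype=complex)
    m = int(mask.sum())
    spec[mask] = rng.normal(size=m) + 1j * rng.normal(size=m)
    x = np.fft.irfft(spec, n)
    cur = np.sqrt(np.mean(x * x))
    if rms == 0 or cur == 0:
        return np.zeros(n)
    return x * (rms / cur)


# ---------------------------------------------------------------------------
# leakage-aware effect planting

@functools.lru_cache(maxsize=4)
def _dwt_band_response(n: int = _SEG_SAMPLES) -> tuple[np.ndarray, np.ndarray]:
    """resp[b, k]: expected fraction of unit-energy content at rfft bin k of an
    n-sample segment that the DWT measures in band b (averaged over phase)."""
    freqs = np.fft.rfftfreq(n, 1.0 / _SEG_FS)
    nb = len(freqs)
    basis = []
    energies = []
    for k in range(nb):
        for phase in (0.0, np.pi / 2):
            spec = np.zeros(nb, dtype=complex)
            spec[k] = np.exp(1j * phase)
            x = np.fft.irfft(spec, n)
            basis.append(x)
            energies.append(np.sum(x * x))
    basis = np.asarray(basis)
    energies = np.asarray(energies)
    _, details = dwt.wavedec(basis, 6)
    resp = np.zeros((len(BANDS), nb))
    for bi, band in enumerate(BANDS):
        e_band = np.sum(details[BAND_LEVELS[band] - 1] ** 2, axis=-1)
        pair_sum = e_band.reshape(nb, 2).sum(axis=1)
        tot = energies.reshape(nb, 2).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            resp[bi] = np.where(tot > 0, pair_sum / tot, 0.0)
    return freqs, resp


class _PlantingModel:
    """Per-spec machinery: spectral shapes, leakage matrix, gain solver."""

    def __init__(self, spec: GeneratorSpec):
        self.spec = spec
        n = spec.n_trial_samples
        self.freqs = np.fft.rfftfreq(n, 1.0 / spec.fs)
        f = self.freqs
        resp_freqs, resp = _dwt_band_response()
        # interpolate the segment-grid response onto the trial grid
        self.resp = np.vstack(
            [np.interp(f, resp_freqs, resp[b]) for b in range(len(BANDS))]
        )
        if spec.bandpass is not None:
            low, high = spec.bandpass
            inband = f <= _SEG_FS / 2
            h2 = np.zeros_like(f)
            h2[inband] = bandpass_magnitude_response(f[inband], low, high, fs=_SEG_FS)
            self.h2 = h2
        else:
            self.h2 = np.ones_like(f)
        noise_dens = np.zeros_like(f)
        pos = f > 0
        noise_dens[pos] = f[pos] ** (-spec.noise_exponent)
        noise_dens[(f < 0.5) | (f > 100.0)] = 0.0
        self.noise_dens = noise_dens
        noise_total = noise_dens.sum()
        w_total = sum(spec.band_profiles.values()) + spec.noise_weight
        seg_energy = spec.rms ** 2 * _SEG_SAMPLES
        self.base_band_e = {
            b: seg_energy * spec.band_profiles[b] / w_total for b in BANDS
        }
        noise_e = seg_energy * spec.noise_weight / w_total
        # per-interval spectral shapes (normalized energy densities) and the
        # noise share of each interval
        self.masks = {}
        self.noise_in_interval = {}
        for iv in INTERVALS:
            lo, hi = INTERVAL_EDGES[iv]
            m = (f >= lo) & (f < hi) if iv != "high" else (f >= lo) & (f <= hi)
            if not m.any():
                raise ValueError(
                    f"trial too short: no spectral bins in interval {iv}"
                )
            self.masks[iv] = m
            self.noise_in_interval[iv] = noise_e * noise_dens[m].sum() / noise_total
        self._solve_cache: dict = {}

    def interval_energies(self, band_gains: np.ndarray) -> np.ndarray:
        """Per-interval energy targets given per-band subject gains (5,)."""
        e = np.empty(len(INTERVALS))
        for j, iv in enumerate(INTERVALS):
            e[j] = self.noise_in_interval[iv]
            if iv in BANDS:
                e[j] += self.base_band_e[iv] * band_gains[BANDS.index(iv)]
        return e

    def shapes(self, band_gains: np.ndarray) -> np.ndarray:
        """s[j, k]: normalized spectral energy shape of interval j."""
        f = self.freqs
        s = np.zeros((len(INTERVALS), len(f)))
        for j, iv in enumerate(INTERVALS):
            m = self.masks[iv]
            dens = self.noise_dens * m
            tot_noise = dens.sum()
            if tot_noise > 0:
                dens = dens / tot_noise * self.noise_in_interval[iv]
            if iv in BANDS:
                be = self.base_band_e[iv] * band_gains[BANDS.index(iv)]
                dens = dens + m / m.sum() * be
            s[j] = dens / dens.sum()
        return s

    def solve_gains(self, band_gains: tuple, deltas: tuple) -> tuple[np.ndarray, np.ndarray]:
        """Interval energy allocations (left, right) realizing measured
        log-ratio ``deltas`` per band with equal post-filter totals."""
        key = (band_gains, deltas)
        if key in self._solve_cache:
            return self._solve_cache[key]
        bg = np.asarray(band_gains)
        e = self.interval_energies(bg)
        s = self.shapes(bg)
        # R[b, j]: measured band-b energy per unit pre-filter energy in interval j
        R = (self.resp * self.h2) @ s.T
        t = s @ self.h2  # post-filter survival fraction per interval
        band_ix = np.array([INTERVALS.index(b) for b in BANDS])
        out_ix = np.array([INTERVALS.index("low"), INTERVALS.index("high")])
        m0 = R @ e
        total = float(t @ e)
        d = np.asarray(deltas)

        def attempt(kappa: float):
            allocs = []
            for sign in (+1.0, -1.0):
                target = np.append(kappa * m0 * np.exp(sign * d / 2.0), total)
                A = np.zeros((6, 6))
                A[:5, :5] = R[:, band_ix]
                A[:5, 5] = R[:, out_ix] @ e[out_ix]
                A[5, :5] = t[band_ix]
                A[5, 5] = t[out_ix] @ e[out_ix]
                sol = np.linalg.solve(A, target)
                if np.any(sol <= 0):
                    return None
                alloc = np.empty(len(INTERVALS))
                alloc[band_ix] = sol[:5]
                alloc[out_ix] = e[out_ix] * sol[5]
                allocs.append(alloc)
            return allocs

        kappa = 1.0
        allocs = attempt(kappa)
        while allocs is None and kappa > 0.1:
            kappa *= 0.9
            allocs = attempt(kappa)
        if allocs is None:
            # no exact realization (extreme subject gains or effects): fall
            # back to the nonnegative least-squares approximation and warn
            import warnings
            from scipy.optimize import nnls

            warnings.warn(
                "asymmetry effect not exactly realizable for this channel "
                "profile; using a least-squares approximation (increase "
                "noise_weight or reduce |log_effect| / subject_sd)",
                stacklevel=2,
            )
            allocs = []
            floor = 1e-3 * e.sum()
            for sign in (+1.0, -1.0):
                target = np.append(0.7 * m0 * np.exp(sign * d / 2.0), total)
                A = np.zeros((6, 6))
                A[:5, :5] = R[:, band_ix]
                A[:5, 5] = R[:, out_ix] @ e[out_ix]
                A[5, :5] = t[band_ix]
                A[5, 5] = t[out_ix] @ e[out_ix]
                sol, _ = nnls(A, target)
                sol = np.maximum(sol, floor / e.sum())
                alloc = np.empty(len(INTERVALS))
                alloc[band_ix] = np.maximum(sol[:5], floor)
                alloc[out_ix] = np.maximum(e[out_ix] * sol[5], floor)
                allocs.append(alloc)
        result = (allocs[0], allocs[1])
        self._solve_cache[key] = result
        return result


def _channel_deltas(spec: GeneratorSpec, emotion: str) -> dict[str, tuple]:
    """Per-channel 5-vector of planted log-effects (left +, right -)."""
    per_pair = np.zeros((len(PAIRED_CHANNELS), len(BANDS)))
    for eff in spec.asymmetry_effects:
        if eff.emotion != emotion:
            continue
        bi = BANDS.index(eff.band)
        for p in eff.pair_indices():
            per_pair[p - 1, bi] += eff.log_effect
    deltas: dict[str, tuple] = {}
    for pi, (left, right) in enumerate(PAIRED_CHANNELS):
        row = tuple(per_pair[pi])
        deltas[left] = row
        deltas[right] = row  # right side is handled by the solver's minus branch
    return deltas


def _gen_channel(
    model: _PlantingModel, alloc: np.ndarray, shapes: np.ndarray,
    rng: np.random.Generator, n: int,
) -> np.ndarray:
    """One channel: per-interval Gaussian content, each interval rescaled to
    its exact energy allocation (per 4 s at 200 Hz, converted to trial scale)."""
    spec_arr = np.zeros(len(model.freqs), dtype=complex)
    # energy targets are per-800-samples-at-200Hz; convert via power
    scale = (n / model.spec.fs) / (_SEG_SAMPLES / _SEG_FS)
    for j, iv in enumerate(INTERVALS):
        m = model.masks[iv]
        z = rng.normal(size=int(m.sum())) + 1j * rng.normal(size=int(m.sum()))
        comp = np.sqrt(shapes[j][m]) * z
        # rfft Parseval: E = (1/n) * (2 * sum |S_k|^2) for interior bins
        nyq = model.freqs[m] == model.spec.fs / 2.0
        w = np.where(nyq, 1.0, 2.0)
        energy = np.sum(w * np.abs(comp) ** 2) / n
        target = alloc[j] * scale
        if energy > 0:
            comp *= np.sqrt(target / energy)
        spec_arr[m] += comp
    return np.fft.irfft(spec_arr, n)


def generate_dataset(spec: GeneratorSpec) -> list[EEGRecording]:
    """Generate the full labeled dataset described by ``spec``.

    Deterministic: identical (spec, seed) reproduces identical data.
    Emotions are balanced within each session.
    """
    model = _PlantingModel(spec)
    n = spec.n_trial_samples
    emotions_cycle = [
        emo for emo in spec.emotions for _ in range(spec.trials_per_session_per_emotion)
    ]
    side_of = {}
    for left, right in PAIRED_CHANNELS:
        side_of[left] = 0
        side_of[right] = 1
    recordings: list[EEGRecording] = []
    for si in range(spec.n_subjects):
        subj_rng = np.random.default_rng([spec.seed, 1000 + si])
        band_gains = tuple(
            np.exp(subj_rng.normal(0.0, spec.subject_sd, size=len(BANDS)))
        )
        shapes = model.shapes(np.asarray(band_gains))
        base_alloc = model.interval_energies(np.asarray(band_gains))
        deltas_by_emotion = {
            emo: _channel_deltas(spec, emo) for emo in spec.emotions
        }
        for sess in range(spec.n_sessions):
            for ti, emotion in enumerate(emotions_cycle):
                trial_rng = np.random.default_rng([spec.seed, si, sess, ti])
                data = np.empty((len(spec.montage), n))
                deltas = deltas_by_emotion[emotion]
                for ci, ch in enumerate(spec.montage):
                    d = deltas.get(ch)
                    if d is None or all(v == 0.0 for v in d):
                        alloc = base_alloc
                    else:
                        pair_alloc = model.solve_gains(band_gains, d)
                        alloc = pair_alloc[side_of[ch]]
                    data[ci] = _gen_channel(model, alloc, shapes, trial_rng, n)
                recordings.append(
                    EEGRecording(
                        data=data,
                        fs=spec.fs,
                        channels=spec.montage,
                        subject_id=f"S{si + 1:02d}",
                        session_id=sess + 1,
                        trial_id=ti + 1,
                        emotion=emotion,
                    )
                )
    return recordings


def write_fixture(recordings, path) -> None:
    """Persist recordings as one array container per trial plus a manifest."""
    from .io import write_recordings

    recordings = list(recordings)
    if not recordings:
        raise ValueError("cannot write an empty recording collection")
    write_recordings(recordings, path)
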