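"""Missing-fundamental (MF) pitch psychophysics.

Harmonic complex tones without spectral energy at their periodicity
frequency F0 are heard either at the (missing) fundamental or at a sounding
harmonic, usually the lowest one present (order ``n_min``), whose frequency
``F_SP = n_min * F0`` is called the spectral pitch.  A listener's habitual
mode is measured with a two-interval task: in each pair the periodicity
frequency moves in the opposite direction of the spectral frequency while
the highest sounding harmonic is shared between the two tones, so a "which
tone was higher" answer reveals which cue dominated.  The per-subject score
is the pitch perception index

    delta_P = (n_SP - n_F0) / (n_SP + n_F0)

ranging from -1 (pure fundamental/periodicity pitch perceiver) to +1 (pure
spectral pitch perceiver).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "HarmonicComplexSpec",
    "SoundPair",
    "TestBattery",
    "ResponseTally",
    "PitchIndexResult",
    "harmonic_levels",
    "synthesize",
    "default_battery_design",
    "build_battery",
    "classify_response",
    "pitch_index",
    "write_wav",
    "battery_manifest",
]

DEFAULT_SAMPLE_RATE = 44100.0
#: peak headroom for normalized waveforms, dB full scale
DEFAULT_HEADROOM_DB = -3.0


@dataclass(frozen=True)
class HarmonicComplexSpec:
    """Parametric description of one missing-fundamental complex tone."""

    f0_hz: float
    n_min: int
    n_harmonics: int
    duration_s: float = 0.6
    fade_s: float = 0.010
    id: str = ""

    def __post_init__(self):
        if self.f0_hz <= 0:
            raise ValueError(f"f0_hz must be positive, got {self.f0_hz}")
        if self.n_min < 2:
            raise ValueError(
                f"n_min must be >= 2 (the fundamental is missing), got {self.n_min}"
            )
        if self.n_harmonics < 1:
            raise ValueError(f"n_harmonics must be >= 1, got {self.n_harmonics}")
        if not object.__getattribute__(self, "id"):
            object.__setattr__(
                self,
                "id",
                f"f{self.f0_hz:.4f}_m{self.n_min}_N{self.n_harmonics}",
            )

    @property
    def orders(self) -> np.ndarray:
        return np.arange(self.n_min, self.n_min + self.n_harmonics)

    @property
    def frequencies_hz(self) -> np.ndarray:
        return self.orders * self.f0_hz

    @property
    def f_sp_hz(self) -> float:
        """Spectral pitch frequency, taken as n_min * F0."""
        return self.n_min * self.f0_hz

    @property
    def spectral_centroid_hz(self) -> float:
        """Alternative spectral-pitch definition: amplitude-weighted centroid."""
        _, freqs, levels = zip(*harmonic_levels(self))
        amps = 10.0 ** (np.asarray(levels) / 20.0)
        return float(np.average(freqs, weights=amps))

    @property
    def highest_harmonic_hz(self) -> float:
        return (self.n_min + self.n_harmonics - 1) * self.f0_hz


@dataclass(frozen=True)
class SoundPair:
    first: HarmonicComplexSpec
    second: HarmonicComplexSpec
    pair_id: str = ""

    def __post_init__(self):
        d_f0 = self.second.f0_hz - self.first.f0_hz
        d_fsp = self.second.f_sp_hz - self.first.f_sp_hz
        if d_f0 == 0 or d_fsp == 0:
            raise ValueError(
                f"pair {self.pair_id!r}: F0 and F_SP must both change between members"
            )
        if np.sign(d_f0) == np.sign(d_fsp):
            raise ValueError(
                f"pair {self.pair_id!r}: F0 and F_SP must move in opposite directions"
            )
        h1, h2 = self.first.highest_harmonic_hz, self.second.highest_harmonic_hz
        if abs(h1 - h2) > 1e-9 * max(h1, h2):
            raise ValueError(
                f"pair {self.pair_id!r}: highest harmonic differs "
                f"({h1:.6f} vs {h2:.6f} Hz)"
            )

    @property
    def delta_f0(self) -> float:
        return self.second.f0_hz - self.first.f0_hz

    @property
    def delta_fsp(self) -> float:
        return self.second.f_sp_hz - self.first.f_sp_hz


@dataclass
class TestBattery:
    pairs: list
    order_seed: int
    isi_s: float = 0.4

    def __len__(self):
        return len(self.pairs)

    @property
    def sound_ids(self) -> set:
        ids = set()
        for p in self.pairs:
            ids.add(p.first.id)
            ids.add(p.second.id)
        return ids


@dataclass(frozen=True)
class ResponseTally:
    n_sp: int
    n_f0: int

    def __post_init__(self):
        if self.n_sp < 0 or self.n_f0 < 0:
            raise ValueError("counts must be nonnegative")


@dataclass(frozen=True)
class PitchIndexResult:
    delta_p: float
    n_classified: int


def _attenuation_db(freq_hz: np.ndarray) -> np.ndarray:
    """Log-linear spectral attenuation: 0 dB up to 1 kHz, -3 dB at 3 kHz,
    a further -17 dB from 3 to 15.9 kHz (-20 dB total), held constant above."""
    f = np.asarray(freq_hz, dtype=float)
    a = np.zeros_like(f)
    lo = (f > 1000.0) & (f <= 3000.0)
    a[lo] = -3.0 * np.log(f[lo] / 1000.0) / np.log(3.0)
    hi = (f > 3000.0) & (f <= 15900.0)
    a[hi] = -3.0 - 17.0 * np.log(f[hi] / 3000.0) / np.log(15900.0 / 3000.0)
    a[f > 15900.0] = -20.0
    return a


def harmonic_levels(spec: HarmonicComplexSpec, sample_rate: float = DEFAULT_SAMPLE_RATE):
    """Component levels of an MF complex: -5 dB per harmonic order above
    n_min plus the log-linear high-frequency attenuation, relative to the
    n_min harmonic before attenuation.

    Returns a list of (order, frequency_hz, level_db) tuples.
    """
    freqs = spec.frequencies_hz
    nyquist = sample_rate / 2.0
    if freqs[-1] >= nyquist:
        bad = spec.orders[freqs >= nyquist][0]
        raise ValueError(
            f"harmonic order {bad} at {bad * spec.f0_hz:.1f} Hz exceeds the "
            f"Nyquist frequency {nyquist:.1f} Hz"
        )
    rolloff = -5.0 * (spec.orders - spec.n_min).astype(float)
    levels = rolloff + _attenuation_db(freqs)
    return list(zip(spec.orders.tolist(), freqs.tolist(), levels.tolist()))


def synthesize(
    spec: HarmonicComplexSpec,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    headroom_db: float = DEFAULT_HEADROOM_DB,
) -> np.ndarray:
    """Render an MF complex as a unit-range waveform (sine phases, linear
    fades, peak-normalized to ``headroom_db`` dBFS)."""
    comps = harmonic_levels(spec, sample_rate)
    n = int(round(spec.duration_s * sample_rate))
    t = np.arange(n) / sample_rate
    x = np.zeros(n)
    for _, f, level in comps:
        x += 10.0 ** (level / 20.0) * np.sin(2 * np.pi * f * t)
    nfade = int(round(spec.fade_s * sample_rate))
    if nfade > 0:
        ramp = np.linspace(0.0, 1.0, nfade, endpoint=False)
        x[:nfade] *= ramp
        x[-nfade:] *= ramp[::-1]
    peak = np.max(np.abs(x))
    if peak > 0:
        x *= 10.0 ** (headroom_db / 20.0) / peak
    return x


def write_wav(path, waveform: np.ndarray, sample_rate: float = DEFAULT_SAMPLE_RATE):
    """Write a [-1, 1] waveform as 16-bit PCM WAV."""
    from scipy.io import wavfile

    pcm = np.clip(waveform, -1.0, 1.0)
    wavfile.write(path, int(sample_rate), (pcm * 32767).astype(np.int16))


# ---------------------------------------------------------------------------
# battery construction


def default_battery_design(
    n_f0: int = 9,
    f0_range=(100.0, 500.0),
    n_min_values=(3, 4, 5, 6, 7, 8),
    n_harmonics_values=(2, 3, 4),
) -> list:
    """Default stimulus grid: log-spaced base F0 crossed with n_min and N.

    Each cell defines a pair whose second member shares the top harmonic:
    with top order m = n_min + N - 1, the partner has n_min' = n_min - 1 and
    f0' = f0 * m / (m - 1), so F0 rises while F_SP falls.  9 x 6 x 3 = 162
    cells, hence 162 pairs / 324 unique sounds.
    """
    f0s = np.geomspace(f0_range[0], f0_range[1], n_f0)
    cells = []
    for f0 in f0s:
        for n_min in n_min_values:
            for big_n in n_harmonics_values:
                cells.append({"f0": float(f0), "n_min": int(n_min), "n_harmonics": int(big_n)})
    return cells


def _pair_from_cell(cell: dict, pair_id: str) -> SoundPair:
    f0, n_min, big_n = cell["f0"], cell["n_min"], cell["n_harmonics"]
    if n_min < 3:
        raise ValueError(
            f"cell {cell}: n_min must be >= 3 so the partner tone keeps a "
            "missing fundamental (n_min' = n_min - 1 >= 2)"
        )
    m = n_min + big_n - 1  # shared top harmonic order of member A
    a = HarmonicComplexSpec(f0_hz=f0, n_min=n_min, n_harmonics=big_n)
    b = HarmonicComplexSpec(
        f0_hz=f0 * m / (m - 1), n_min=n_min - 1, n_harmonics=big_n
    )
    # b: F0 up by m/(m-1); top order m-1 -> identical top frequency; F_SP down
    return SoundPair(first=a, second=b, pair_id=pair_id)


def build_battery(
    design: list | None = None,
    order_seed: int = 0,
    isi_s: float = 0.4,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
) -> TestBattery:
    """Build the paired MF test battery from a design grid.

    Pair order and within-pair order are pseudo-randomized by ``order_seed``
    and are deterministic given (design, seed).
    """
    if design is None:
        design = default_battery_design()
    pairs = []
    for i, cell in enumerate(design):
        pairs.append(_pair_from_cell(cell, pair_id=f"pair{i:03d}"))
    for p in pairs:
        for member in (p.first, p.second):
            harmonic_levels(member, sample_rate)  # aliasing check
    rng = np.random.default_rng(order_seed)
    order = rng.permutation(len(pairs))
    flip = rng.random(len(pairs)) < 0.5
    shuffled = []
    for rank, idx in enumerate(order):
        p = pairs[idx]
        if flip[idx]:
            p = SoundPair(first=p.second, second=p.first, pair_id=p.pair_id)
        shuffled.append(p)
    ids = TestBattery(pairs=shuffled, order_seed=order_seed, isi_s=isi_s).sound_ids
    if len(ids) != 2 * len(shuffled):
        raise ValueError(
            f"design produced {len(ids)} unique sounds for {len(shuffled)} pairs; "
            "every pair member must be unique"
        )
    return TestBattery(pairs=shuffled, order_seed=order_seed, isi_s=isi_s)


def battery_manifest(battery: TestBattery) -> pd.DataFrame:
    """Tabular manifest: one row per pair with member parameters and the
    direction of F0 and F_SP from first to second member."""
    rows = []
    for presented, p in enumerate(battery.pairs):
        rows.append(
            {
                "presentation": presented,
                "pair_id": p.pair_id,
                "first_id": p.first.id,
                "second_id": p.second.id,
                "first_f0": p.first.f0_hz,
                "second_f0": p.second.f0_hz,
                "first_n_min": p.first.n_min,
                "second_n_min": p.second.n_min,
                "first_N": p.first.n_harmonics,
                "second_N": p.second.n_harmonics,
                "first_f_sp": p.first.f_sp_hz,
                "second_f_sp": p.second.f_sp_hz,
                "f0_direction": int(np.sign(p.delta_f0)),
                "f_sp_direction": int(np.sign(p.delta_fsp)),
            }
        )
    return pd.DataFrame(rows)


def manifest_hash(battery: TestBattery) -> str:
    csv = battery_manifest(battery).to_csv(index=False)
    return hashlib.sha256(csv.encode()).hexdigest()


def save_design(design: list, path):
    with open(path, "w") as fh:
        yaml.safe_dump({"cells": design}, fh)


def load_design(path) -> list:
    with open(path) as fh:
        return yaml.safe_load(fh)["cells"]


# ---------------------------------------------------------------------------
# scoring


def classify_response(pair: SoundPair, answer: str) -> str:
    """Map a "which tone was higher" answer onto the pitch cue it followed.

    ``answer`` is "first_higher" or "second_higher".  If the reported
    direction matches the sign of the F0 change the response is
    "fundamental"; if it matches the F_SP change it is "spectral".  The pair
    construction guarantees exactly one matches.
    """
    if answer not in ("first_higher", "second_higher"):
        raise ValueError(f"unknown answer {answer!r}")
    reported = 1 if answer == "second_higher" else -1
    if reported == np.sign(pair.delta_f0):
        return "fundamental"
    return "spectral"


def pitch_index(tally: ResponseTally) -> PitchIndexResult:
    """Pitch perception index delta_P = (n_SP - n_F0) / (n_SP + n_F0)."""
    total = tally.n_sp + tally.n_f0
    if total == 0:
        raise ValueError("pitch index undefined for zero classified responses")
    return PitchIndexResult(
        delta_p=(tally.n_sp - tally.n_f0) / total, n_classified=total
    )


def score_responses(battery: TestBattery, answers: dict) -> PitchIndexResult:
    """Score a response log {pair_id: answer} against a battery."""
    by_id = {p.pair_id: p for p in battery.pairs}
    n_sp = n_f0 = 0
    for pid, answer in answers.items():
        kind = classify_response(by_id[pid], answer)
        if kind == "spectral":
            n_sp += 1
        else:
            n_f0 += 1
    return pitch_index(ResponseTally(n_sp=n_sp, n_f0=n_f0))
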