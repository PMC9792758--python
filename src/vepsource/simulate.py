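"""Synthetic color-VEP EEG generator and paradigm bookkeeping.

Emulates the study design every downstream stage expects: 20 subjects, three
color-pair "teams" (RG, RB, GB), 3 trials per team, 70 one-second epochs per
trial (35 per color), 59 channels at 1000 Hz.  Each stimulus drives a fixed
posterior ground-truth dipole with a color-specific ERP template (first-peak
latencies 180 / 185 / 205 ms for red / green / blue); the scalp signal is the
linear forward projection of that moment plus 1/f ("pink") noise, white sensor
noise, 50 Hz line interference, and occasional frontal eye-blink bursts.

The generator is linear in the dipole moment and bit-reproducible under a
fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from ._edf import quantization_step, read_edf, write_edf
from .errors import GeometryError, MontageError
from .localize import Dipole, scalp_potentials
from .montage import Montage, build_standard_montage

COLORS = ("red", "green", "blue")
TEAMS = {"RG": ("red", "green"), "RB": ("red", "blue"),
         "GB": ("green", "blue")}

#: Ground-truth source of the default simulation: a single dipole under the
#: midline parieto-occipital scalp, oriented in the sagittal plane so that its
#: orientation line passes through the calcarine target ball and its scalp
#: pattern peaks on Pz/POz/Oz.
_ANG = np.deg2rad(160.0)
GROUND_TRUTH_POSITION = np.array([0.0, -0.0575, 0.0375])
GROUND_TRUTH_ORIENTATION = np.array([0.0, -np.sin(_ANG), np.cos(_ANG)])


def ground_truth_dipole(moment: float = 1.0) -> Dipole:
    """The generator's source dipole with moment magnitude ``moment`` (A*m)."""
    return Dipole(r0=GROUND_TRUTH_POSITION.copy(),
                  p=GROUND_TRUTH_ORIENTATION * moment)


@dataclass(frozen=True)
class ColorSpec:
    name: str
    rgb: tuple[int, int, int]
    hue_deg: float
    saturation: float = 1.0   # metadata only
    lightness: float = 0.5


DEFAULT_COLORS = (
    ColorSpec("red", (255, 0, 0), 0.0),
    ColorSpec("green", (0, 255, 0), 120.0),
    ColorSpec("blue", (0, 0, 255), 240.0),
)


@dataclass(frozen=True)
class Paradigm:
    """Study design parameters."""

    colors: tuple[ColorSpec, ...] = DEFAULT_COLORS
    pairs: tuple[str, ...] = ("RG", "RB", "GB")
    epochs_per_color_per_trial: int = 35
    trials_per_team: int = 3
    epoch_duration_ms: int = 1000
    baseline_ms: int = 200
    n_subjects: int = 20

    def __post_init__(self) -> None:
        for v in (self.epochs_per_color_per_trial, self.trials_per_team,
                  self.epoch_duration_ms, self.baseline_ms, self.n_subjects):
            if int(v) != v or v <= 0:
                raise ValueError("design counts must be positive integers")


@dataclass(frozen=True)
class DesignSummary:
    epochs_per_trial: int
    epochs_per_team: int
    epochs_per_subject: int
    team_ms: int
    subject_ms: int
    rest_epochs_per_team: int
    train_per_repeat: int
    test_per_repeat: int


def count_design(paradigm: Paradigm) -> DesignSummary:
    """Deterministic bookkeeping of the paradigm (epoch and time totals)."""
    per_trial = 2 * paradigm.epochs_per_color_per_trial
    per_team = paradigm.trials_per_team * per_trial
    per_subject = len(paradigm.pairs) * per_team
    team_ms = per_team * paradigm.epoch_duration_ms
    return DesignSummary(
        epochs_per_trial=per_trial,
        epochs_per_team=per_team,
        epochs_per_subject=per_subject,
        team_ms=team_ms,
        subject_ms=len(paradigm.pairs) * team_ms,
        rest_epochs_per_team=per_team,
        train_per_repeat=per_team - round(0.2 * per_team),
        test_per_repeat=round(0.2 * per_team),
    )


@dataclass(frozen=True)
class ErpTemplate:
    """Color-specific ERP template: biphasic Gaussian-windowed bump.

    The positive main lobe peaks at ``peak_latency_ms``; a smaller negative
    pre-lobe precedes it by 60 ms.  ``source_amplitude`` is the peak dipole
    moment in A*m.
    """

    color: str
    peak_latency_ms: float
    peak_width_ms: float = 25.0
    source_amplitude: float = 6e-8

    def __post_init__(self) -> None:
        if not 0 < self.peak_latency_ms < 500:
            raise ValueError("peak latency must lie in (0, 500) ms")
        if self.peak_width_ms <= 0 or self.source_amplitude <= 0:
            raise ValueError("width and amplitude must be positive")


def default_templates(amplitude_scale: float = 1.0) -> dict[str, ErpTemplate]:
    """Templates matching the study's latency medians, with a 20% amplitude
    contrast between pair members for linear decodability."""
    base = 6e-8 * amplitude_scale
    return {
        "red": ErpTemplate("red", 180.0, source_amplitude=base),
        "green": ErpTemplate("green", 185.0, source_amplitude=1.2 * base),
        "blue": ErpTemplate("blue", 205.0, source_amplitude=0.8 * base),
    }


def make_erp_template(template: ErpTemplate | str, fs: float,
                      duration_ms: float = 1000.0) -> np.ndarray:
    """Sample a template at ``fs`` over [0, duration_ms) from stimulus onset.

    Unit peak amplitude (scale by ``source_amplitude`` for a moment series);
    global absolute maximum at the peak latency, decayed below 5% of the peak
    by 800 ms.
    """
    if isinstance(template, str):
        if template not in COLORS:
            raise ValueError(f"unknown color {template!r}")
        template = default_templates()[template]
    n = int(round(duration_ms / 1000.0 * fs))
    t = np.arange(n) / fs * 1000.0  # ms since onset
    mu, sd = template.peak_latency_ms, template.peak_width_ms
    wave = np.exp(-0.5 * ((t - mu) / sd) ** 2)
    wave -= 0.3 * np.exp(-0.5 * ((t - (mu - 60.0)) / (0.6 * sd)) ** 2)
    wave[t <= 0.0] = 0.0
    return wave


@dataclass(frozen=True)
class NoiseModel:
    """Additive noise: 1/f background, white sensor noise, 50 Hz line, and
    eye-blink bursts on the six most anterior channels.  Amplitudes in uV."""

    pink_sd: float = 4.0
    white_sd: float = 1.5
    line_amp_50hz: float = 5.0
    blink_rate_per_min: float = 2.0
    blink_amp: float = 120.0

    def __post_init__(self) -> None:
        for v in (self.pink_sd, self.white_sd, self.line_amp_50hz,
                  self.blink_rate_per_min, self.blink_amp):
            if v < 0:
                raise ValueError("noise parameters must be non-negative")

    def silent(self) -> "NoiseModel":
        return replace(self, pink_sd=0.0, white_sd=0.0, line_amp_50hz=0.0,
                       blink_rate_per_min=0.0)


@dataclass(frozen=True)
class Event:
    onset: int        # sample index
    label: str        # color
    trial: int        # 0-based trial within the team
    team: str


@dataclass
class ContinuousRecording:
    """Continuous EEG: channels x samples in microvolts, with labeled events."""

    fs: float
    data: np.ndarray
    events: list[Event]
    montage: Montage
    subject: int = 0
    team: str = ""

    def __post_init__(self) -> None:
        if self.data.shape[0] != len(self.montage.channels):
            raise MontageError("data row count must match the montage")
        onsets = [e.onset for e in self.events]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("event onsets must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def _pink_noise(rng: np.random.Generator, n_ch: int, n: int,
                fs: float) -> np.ndarray:
    """1/f-shaped Gaussian noise, unit variance per channel."""
    white = rng.standard_normal((n_ch, n))
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    shaping = np.zeros_like(f)
    shaping[1:] = 1.0 / np.sqrt(f[1:])
    shaped = np.fft.irfft(spec * shaping[None, :], n=n, axis=1)
    sd = shaped.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return shaped / sd


def simulate_subject(paradigm: Paradigm, team: str,
                     dipole: Dipole | None = None,
                     templates: dict[str, ErpTemplate] | None = None,
                     noise: NoiseModel | None = None,
                     montage: Montage | None = None,
                     seed: int = 0, subject: int = 0,
                     lead_in_s: float = 1.0, gap_s: float = 2.0,
                     fs: float = 1000.0) -> ContinuousRecording:
    """Simulate one subject's continuous recording for one color-pair team.

    Every event adds the color's template (scaled to its source amplitude)
    along the dipole moment; the scalp signal is the noise-free forward
    projection plus the noise model's terms.  Event order within each trial
    is a seeded random interleave of exactly 35+35 color labels (under the
    default design).  Identical seeds give identical output.
    """
    if team not in TEAMS:
        raise ValueError(f"unknown team {team!r}; expected one of {TEAMS}")
    montage = montage or build_standard_montage()
    if dipole is None:
        dipole = ground_truth_dipole()
    if np.linalg.norm(dipole.r0) >= montage.sphere_radius:
        raise GeometryError("source dipole must lie inside the head sphere")
    templates = templates or default_templates()
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed)

    epoch_n = int(round(paradigm.epoch_duration_ms / 1000.0 * fs))
    base_n = int(round(paradigm.baseline_ms / 1000.0 * fs))
    lead_n = max(int(round(lead_in_s * fs)), base_n)
    gap_n = int(round(gap_s * fs))
    per_trial = 2 * paradigm.epochs_per_color_per_trial
    colors = TEAMS[team]

    events: list[Event] = []
    cursor = lead_n
    for trial in range(paradigm.trials_per_team):
        labels = np.array([colors[0]] * paradigm.epochs_per_color_per_trial
                          + [colors[1]] * paradigm.epochs_per_color_per_trial)
        rng.shuffle(labels)
        for k in range(per_trial):
            events.append(Event(onset=cursor + k * epoch_n,
                                label=str(labels[k]), trial=trial, team=team))
        cursor += per_trial * epoch_n + gap_n
    n_total = cursor - gap_n + epoch_n + base_n

    # forward projection: scalp pattern per unit moment along the orientation
    p_hat = dipole.p / np.linalg.norm(dipole.p) if np.linalg.norm(dipole.p) \
        else dipole.p
    pattern = scalp_potentials(Dipole(r0=dipole.r0, p=p_hat), montage)  # V/(A*m)
    moment_scale = float(np.linalg.norm(dipole.p))  # 1.0 for the unit default

    data = np.zeros((len(montage.channels), n_total))
    waves = {c: make_erp_template(templates[c], fs,
                                  paradigm.epoch_duration_ms) for c in colors}
    for ev in events:
        amp = templates[ev.label].source_amplitude * moment_scale
        seg = waves[ev.label] * amp              # A*m over the epoch
        data[:, ev.onset:ev.onset + epoch_n] += pattern[:, None] * seg[None, :]
    data *= 1e6  # V -> uV

    n_ch = data.shape[0]
    if noise.pink_sd > 0:
        data += noise.pink_sd * _pink_noise(rng, n_ch, n_total, fs)
    if noise.white_sd > 0:
        data += noise.white_sd * rng.standard_normal((n_ch, n_total))
    if noise.line_amp_50hz > 0:
        t = np.arange(n_total) / fs
        phase = rng.uniform(0, 2 * np.pi)
        data += noise.line_amp_50hz * np.sin(2 * np.pi * 50.0 * t + phase)
    if noise.blink_rate_per_min > 0 and noise.blink_amp > 0:
        anterior = np.argsort(-montage.positions[:, 1])[:6]
        weights = np.linspace(1.0, 0.5, 6)
        n_blinks = rng.poisson(noise.blink_rate_per_min * n_total / fs / 60.0)
        blink_n = int(round(0.4 * fs))
        burst = np.sin(np.pi * np.arange(blink_n) / blink_n)
        for _ in range(n_blinks):
            start = int(rng.integers(0, max(n_total - blink_n, 1)))
            for ch, wt in zip(anterior, weights):
                data[ch, start:start + blink_n] += noise.blink_amp * wt \
                    * burst[:n_total - start][:blink_n]

    return ContinuousRecording(fs=fs, data=data, events=events,
                               montage=montage, subject=subject, team=team)


def write_recording(recording: ContinuousRecording, path: str | Path) -> None:
    """Write the continuous data as EDF plus a companion events TSV."""
    path = Path(path)
    write_edf(path, recording.data, recording.fs,
              [c.name for c in recording.montage.channels])
    lines = ["onset_sample\tlabel\ttrial\tteam"]
    lines += [f"{e.onset}\t{e.label}\t{e.trial}\t{e.team}"
              for e in recording.events]
    path.with_suffix(path.suffix + ".events.tsv").write_text(
        "\n".join(lines) + "\n")


def read_recording(path: str | Path,
                   montage: Montage | None = None) -> ContinuousRecording:
    """Read an EDF + events TSV pair written by :func:`write_recording`."""
    path = Path(path)
    montage = montage or build_standard_montage()
    data, fs, _names = read_edf(path)
    if data.shape[0] != len(montage.channels):
        raise MontageError(
            f"file has {data.shape[0]} signals, montage expects "
            f"{len(montage.channels)}")
    events_path = path.with_suffix(path.suffix + ".events.tsv")
    if not events_path.exists():
        raise IOError(f"missing companion events file {events_path}")
    events = []
    for line in events_path.read_text().splitlines()[1:]:
        onset, label, trial, team = line.split("\t")
        events.append(Event(onset=int(onset), label=label,
                            trial=int(trial), team=team))
    return ContinuousRecording(fs=fs, data=data, events=events,
                               montage=montage,
                               team=events[0].team if events else "")


def edf_quantization_step(recording: ContinuousRecording) -> np.ndarray:
    """Per-channel quantization step a round trip through EDF incurs."""
    return quantization_step(recording.data)
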