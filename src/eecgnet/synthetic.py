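"""Synthetic multi-subject ECG cohorts.

Each subject is a fixed PQRST template: five Gaussian bumps (P, Q, R, S, T)
positioned relative to the R peak, repeated at a jittered RR interval.  On top
of the clean beat train the generator adds the artifact classes that the
preprocessing stage is designed to remove: slow sinusoidal baseline wander,
sparse spikes, and white sensor noise.  Two cohort shapes are emulated:

* "MIT-like"  — two leads at 360 Hz,
* "CU-like"   — one lead at 500 Hz.

All randomness flows from integer seeds through ``numpy.random.default_rng``;
every output is a pure function of (arguments, seed).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SubjectTemplate",
    "NoiseSpec",
    "ECGRecord",
    "LabeledCohort",
    "make_subject_template",
    "synthesize_record",
    "generate_cohort",
    "write_cohort",
]

# Physiological-looking draw ranges for template randomization (seconds, mV).
# Centers are offsets from the R peak; R itself is pinned at 0 with the
# dominant positive amplitude so that R-peak detection is always well posed.
_WAVE_NAMES = ("P", "Q", "R", "S", "T")
_CENTER_RANGES = {
    "P": (-0.22, -0.16),
    "Q": (-0.055, -0.035),
    "R": (0.0, 0.0),
    "S": (0.035, 0.055),
    "T": (0.24, 0.32),
}
_AMP_RANGES = {
    "P": (0.08, 0.18),
    "Q": (-0.20, -0.08),
    "R": (1.1, 1.8),
    "S": (-0.35, -0.12),
    "T": (0.20, 0.40),
}
_WIDTH_RANGES = {
    "P": (0.020, 0.030),
    "Q": (0.008, 0.014),
    "R": (0.012, 0.022),
    "S": (0.010, 0.016),
    "T": (0.040, 0.060),
}
_RR_RANGE = (0.7, 1.0)  # mean RR interval, seconds (60-86 bpm)
_RR_JITTER_SD = 0.02    # seconds

# Mixing applied to the clean wave components to form the second lead:
# scaled 0.6x overall with P and T inverted, so inter-lead correlation exists
# but the QRS polarity (hence R-peak detection) is preserved.
_LEAD2_SCALE = 0.6
_LEAD2_WAVE_SIGNS = np.array([-1.0, 1.0, 1.0, 1.0, -1.0])


@dataclass(frozen=True)
class SubjectTemplate:
    """Per-subject PQRST morphology: five Gaussians relative to the R peak."""

    wave_centers: np.ndarray    # (5,) seconds, strictly increasing, R at 0
    wave_amplitudes: np.ndarray  # (5,) mV, R largest in magnitude and positive
    wave_widths: np.ndarray     # (5,) seconds, > 0
    base_rr: float              # seconds, > 0
    rr_jitter_sd: float         # seconds, >= 0

    def __post_init__(self) -> None:
        c = np.asarray(self.wave_centers, dtype=float)
        a = np.asarray(self.wave_amplitudes, dtype=float)
        w = np.asarray(self.wave_widths, dtype=float)
        if c.shape != (5,) or a.shape != (5,) or w.shape != (5,):
            raise ValueError("template needs exactly 5 waves (P,Q,R,S,T)")
        if not np.all(np.diff(c) > 0) or c[2] != 0.0:
            raise ValueError("wave centers must be strictly increasing with R at 0")
        if not np.all(w > 0):
            raise ValueError("wave widths must be positive")
        r_amp = a[2]
        others = np.delete(a, 2)
        if not (r_amp > 0 and np.all(r_amp > np.abs(others))):
            raise ValueError("R amplitude must be positive and dominate |P|,|Q|,|S|,|T|")
        if self.base_rr <= 0:
            raise ValueError("base_rr must be positive")
        if self.rr_jitter_sd < 0:
            raise ValueError("rr_jitter_sd must be non-negative")
        object.__setattr__(self, "wave_centers", c)
        object.__setattr__(self, "wave_amplitudes", a)
        object.__setattr__(self, "wave_widths", w)


@dataclass(frozen=True)
class NoiseSpec:
    """Additive artifact model: baseline wander + white noise + sparse spikes."""

    baseline_wander_amp: float = 0.1   # mV
    baseline_wander_freq: float = 0.25  # Hz
    white_noise_sd: float = 0.05       # mV
    spike_rate: float = 0.1            # spikes per second
    spike_amp: float = 0.5             # mV

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be non-negative")

    @classmethod
    def clean(cls) -> "NoiseSpec":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass
class ECGRecord:
    """A multi-lead sampled signal in mV with its sampling rate and label."""

    samples: np.ndarray        # (n_samples, n_leads) mV
    fs: float                  # Hz
    subject_id: str
    lead_names: list[str] = field(default_factory=list)
    record_id: str = ""
    r_positions: np.ndarray | None = None  # planted R-peak sample indices

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (n_samples, n_leads) array")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.samples.shape[1] < 1:
            raise ValueError("at least one lead required")
        if not self.lead_names:
            self.lead_names = [f"lead{i + 1}" for i in range(self.samples.shape[1])]
        if len(self.lead_names) != self.samples.shape[1]:
            raise ValueError("lead_names length must match number of leads")

    @property
    def n_leads(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.samples.shape[0] / self.fs


@dataclass
class LabeledCohort:
    """Records plus a deterministic train/test assignment."""

    records: list[ECGRecord]
    split_assignment: list[str]  # "train" / "test", parallel to records

    def __post_init__(self) -> None:
        if len(self.records) != len(self.split_assignment):
            raise ValueError("split assignment must be parallel to records")
        if not set(self.split_assignment) <= {"train", "test"}:
            raise ValueError("split labels must be 'train' or 'test'")

    def subset(self, split: str) -> list[ECGRecord]:
        return [r for r, s in zip(self.records, self.split_assignment) if s == split]

    @property
    def subjects(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.subject_id, None)
        return list(seen)


def make_subject_template(seed: int) -> SubjectTemplate:
    """Draw a subject's PQRST template from fixed physiological ranges.

    Deterministic in ``seed``; distinct seeds give distinct draws with
    probability 1.  The R amplitude range dominates the other wave ranges so
    the dominance invariant holds for every draw.
    """
    rng = np.random.default_rng(seed)
    centers, amps, widths = [], [], []
    for name in _WAVE_NAMES:
        lo, hi = _CENTER_RANGES[name]
        centers.append(lo if lo == hi else rng.uniform(lo, hi))
        amps.append(rng.uniform(*_AMP_RANGES[name]))
        widths.append(rng.uniform(*_WIDTH_RANGES[name]))
    base_rr = rng.uniform(*_RR_RANGE)
    return SubjectTemplate(
        wave_centers=np.array(centers),
        wave_amplitudes=np.array(amps),
        wave_widths=np.array(widths),
        base_rr=base_rr,
        rr_jitter_sd=_RR_JITTER_SD,
    )


def _clean_beat_train(
    template: SubjectTemplate,
    n_samples: int,
    fs: float,
    rng: np.random.Generator,
    wave_signs: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sum-of-Gaussians beat train; returns (signal, planted R sample indices).

    The first R peak sits at base_rr/2 so a duration of k*base_rr contains
    exactly k whole beats.
    """
    t = np.arange(n_samples) / fs
    signal = np.zeros(n_samples)
    r_times = []
    r_time = template.base_rr / 2.0
    while r_time < t[-1] + 1.0 / fs:
        r_times.append(r_time)
        jitter = rng.normal(0.0, template.rr_jitter_sd) if template.rr_jitter_sd > 0 else 0.0
        rr = max(0.2, template.base_rr + jitter)
        r_time = r_time + rr
    signs = np.ones(5) if wave_signs is None else wave_signs
    for rt in r_times:
        for c, a, w, s in zip(
            template.wave_centers, template.wave_amplitudes, template.wave_widths, signs
        ):
            mu = rt + c
            lo = max(0, int((mu - 5 * w) * fs))
            hi = min(n_samples, int((mu + 5 * w) * fs) + 1)
            if lo >= hi:
                continue
            tt = t[lo:hi]
            signal[lo:hi] += s * a * np.exp(-0.5 * ((tt - mu) / w) ** 2)
    r_idx = np.round(np.array(r_times) * fs).astype(int)
    r_idx = r_idx[r_idx < n_samples]
    return signal, r_idx


def _noise_trace(
    noise: NoiseSpec, n_samples: int, fs: float, rng: np.random.Generator
) -> np.ndarray:
    t = np.arange(n_samples) / fs
    out = np.zeros(n_samples)
    if noise.baseline_wander_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        out += noise.baseline_wander_amp * np.sin(
            2 * np.pi * noise.baseline_wander_freq * t + phase
        )
    if noise.white_noise_sd > 0:
        out += rng.normal(0.0, noise.white_noise_sd, n_samples)
    if noise.spike_rate > 0 and noise.spike_amp > 0:
        n_spikes = rng.poisson(noise.spike_rate * n_samples / fs)
        if n_spikes:
            pos = rng.integers(0, n_samples, n_spikes)
            sign = rng.choice([-1.0, 1.0], n_spikes)
            out[pos] += sign * noise.spike_amp
    return out


def synthesize_record(
    template: SubjectTemplate,
    duration: float,
    fs: float,
    noise: NoiseSpec,
    seed: int,
    n_leads: int = 1,
    subject_id: str = "S0",
    record_id: str = "",
) -> ECGRecord:
    """Render one record: jittered beat train + per-lead independent noise.

    The second lead, when requested, is the clean wave train rebuilt with
    P/T inverted and scaled 0.6x, plus its own noise draw.
    """
    if duration < 3 * template.base_rr:
        raise ValueError("duration must cover at least 3 beats (3 * base_rr)")
    if n_leads not in (1, 2):
        raise ValueError("1 or 2 leads supported")
    n_samples = int(round(duration * fs))
    rng = np.random.default_rng(seed)
    beat_rng = np.random.default_rng(rng.integers(0, 2**31))
    lead_rngs = [np.random.default_rng(rng.integers(0, 2**31)) for _ in range(n_leads)]

    # Both leads share the beat timing (same heart), hence one jitter stream.
    jitter_state = beat_rng
    clean1, r_idx = _clean_beat_train(template, n_samples, fs, jitter_state)
    leads = [clean1 + _noise_trace(noise, n_samples, fs, lead_rngs[0])]
    if n_leads == 2:
        rebuild_rng = np.random.default_rng(seed)
        rebuild_beat_rng = np.random.default_rng(rebuild_rng.integers(0, 2**31))
        clean2, _ = _clean_beat_train(
            template, n_samples, fs, rebuild_beat_rng, wave_signs=_LEAD2_WAVE_SIGNS
        )
        leads.append(_LEAD2_SCALE * clean2 + _noise_trace(noise, n_samples, fs, lead_rngs[1]))
    return ECGRecord(
        samples=np.column_stack(leads),
        fs=fs,
        subject_id=subject_id,
        record_id=record_id,
        r_positions=r_idx,
    )


def generate_cohort(
    n_subjects: int,
    records_per_subject: int,
    duration: float,
    fs: float,
    noise: NoiseSpec,
    seed: int,
    n_leads: int = 1,
    rr_jitter_sd: float | None = None,
) -> LabeledCohort:
    """Labeled cohort: one template per subject, alternating train/test split.

    Within a subject all records share the template and differ only in the
    noise/jitter seed; even record indices go to train, odd to test, so the
    split fraction is exactly 0.5 and every subject appears in both splits.
    ``rr_jitter_sd`` overrides each template's beat-timing jitter (0 plus a
    zero ``noise`` makes within-subject records bitwise identical).
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    if records_per_subject < 2:
        raise ValueError("need at least 2 records per subject")
    master = np.random.default_rng(seed)
    records: list[ECGRecord] = []
    split: list[str] = []
    for s in range(n_subjects):
        template = make_subject_template(int(master.integers(0, 2**31)))
        if rr_jitter_sd is not None:
            template = dataclasses.replace(template, rr_jitter_sd=rr_jitter_sd)
        sid = f"S{s:03d}"
        for r in range(records_per_subject):
            rec = synthesize_record(
                template,
                duration,
                fs,
                noise,
                seed=int(master.integers(0, 2**31)),
                n_leads=n_leads,
                subject_id=sid,
                record_id=f"{sid}_r{r:03d}",
            )
            records.append(rec)
            split.append("train" if r % 2 == 0 else "test")
    return LabeledCohort(records=records, split_assignment=split)


def write_cohort(cohort: LabeledCohort, out_dir: str | Path) -> Path:
    """Serialize a cohort: one delimited text file per record plus a manifest.

    Each record file has one row per sample and one column per lead; the
    manifest table carries (record_id, subject_id, fs, split, n_leads).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec, split in zip(cohort.records, cohort.split_assignment):
        fname = f"{rec.record_id}.csv"
        np.savetxt(out / fname, rec.samples, delimiter=",", fmt="%.9g")
        rows.append(
            {
                "record_id": rec.record_id,
                "subject_id": rec.subject_id,
                "fs": rec.fs,
                "split": split,
                "n_leads": rec.n_leads,
                "file": fname,
            }
        )
    pd.DataFrame(rows).to_csv(out / "manifest.csv", index=False)
    return out
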