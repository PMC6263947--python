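"""Readers for ECG signal files.

Two input routes: a minimal read-only WFDB reader covering the header plus
signal formats 212 (packed 12-bit pairs, the MIT-BIH layout) and 16
(little-endian int16), and a delimited-text reader for plain numeric matrices
(one row per sample, one column per lead).  Samples are converted to mV as
(adc - baseline) / gain.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import ECGRecord, LabeledCohort

__all__ = [
    "read_wfdb_record",
    "read_delimited_record",
    "read_cohort",
]

_DEFAULT_GAIN = 200.0  # WFDB convention when the header gain is 0/absent


def _parse_gain_field(field: str) -> tuple[float, float | None]:
    """Parse 'gain(baseline)/units' -> (gain, baseline or None)."""
    m = re.match(r"^(-?[\d.]+)(?:\((-?\d+)\))?(?:/(\S+))?$", field)
    if not m:
        raise ValueError(f"cannot parse gain field {field!r}")
    gain = float(m.group(1))
    baseline = float(m.group(2)) if m.group(2) is not None else None
    return (gain if gain != 0 else _DEFAULT_GAIN), baseline


def _decode_fmt212(raw: bytes, n_sig: int, n_samp: int) -> np.ndarray:
    need = (n_samp * n_sig + 1) // 2 * 3
    if len(raw) < need:
        raise ValueError(f"format-212 signal file truncated: have {len(raw)} bytes, need {need}")
    b = np.frombuffer(raw[:need], dtype=np.uint8).astype(np.int32)
    b0, b1, b2 = b[0::3], b[1::3], b[2::3]
    s0 = ((b1 & 0x0F) << 8) | b0
    s1 = ((b1 & 0xF0) << 4) | b2
    s0 = np.where(s0 > 2047, s0 - 4096, s0)
    s1 = np.where(s1 > 2047, s1 - 4096, s1)
    flat = np.empty(s0.size + s1.size, dtype=np.int32)
    flat[0::2], flat[1::2] = s0, s1
    flat = flat[: n_samp * n_sig]
    return flat.reshape(n_samp, n_sig)


def _decode_fmt16(raw: bytes, n_sig: int, n_samp: int) -> np.ndarray:
    need = n_samp * n_sig * 2
    if len(raw) < need:
        raise ValueError(f"format-16 signal file truncated: have {len(raw)} bytes, need {need}")
    flat = np.frombuffer(raw[:need], dtype="<i2").astype(np.int32)
    return flat.reshape(n_samp, n_sig)


def read_wfdb_record(path: str | Path) -> ECGRecord:
    """Read a WFDB header/signal pair (formats 212 and 16) into mV.

    ``path`` is the record path with or without the ``.hea`` suffix; the
    subject id is the record name.
    """
    hea = Path(str(path).removesuffix(".hea") + ".hea")
    if not hea.exists():
        raise FileNotFoundError(f"missing WFDB header {hea}")
    lines = [
        ln.strip() for ln in hea.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    head = lines[0].split()
    if len(head) < 4:
        raise ValueError(f"malformed WFDB header line in {hea}: {lines[0]!r}")
    record_name, n_sig = head[0], int(head[1])
    fs = float(head[2].split("/")[0])
    n_samp = int(head[3])
    if len(lines) - 1 < n_sig:
        raise ValueError(f"header {hea} declares {n_sig} signals but lists {len(lines) - 1}")

    sig_specs = []
    for ln in lines[1 : 1 + n_sig]:
        parts = ln.split()
        fname, fmt = parts[0], parts[1].split("x")[0].split(":")[0].split("+")[0]
        gain, baseline = _parse_gain_field(parts[2]) if len(parts) > 2 else (_DEFAULT_GAIN, None)
        adc_zero = float(parts[4]) if len(parts) > 4 else 0.0
        desc = " ".join(parts[8:]) if len(parts) > 8 else f"sig{len(sig_specs)}"
        sig_specs.append(
            {
                "file": fname,
                "fmt": int(fmt),
                "gain": gain,
                "baseline": baseline if baseline is not None else adc_zero,
                "name": desc,
            }
        )
    files = {s["file"] for s in sig_specs}
    if len(files) != 1:
        raise ValueError("multi-file WFDB records are not supported")
    fmts = {s["fmt"] for s in sig_specs}
    if len(fmts) != 1:
        raise ValueError("mixed signal formats are not supported")
    fmt = fmts.pop()
    dat = hea.parent / sig_specs[0]["file"]
    if not dat.exists():
        raise FileNotFoundError(f"missing WFDB signal file {dat}")
    raw = dat.read_bytes()
    if fmt == 212:
        adc = _decode_fmt212(raw, n_sig, n_samp)
    elif fmt == 16:
        adc = _decode_fmt16(raw, n_sig, n_samp)
    else:
        raise ValueError(f"unsupported WFDB signal format {fmt} (only 212 and 16)")
    mv = np.column_stack(
        [
            (adc[:, i] - sig_specs[i]["baseline"]) / sig_specs[i]["gain"]
            for i in range(n_sig)
        ]
    )
    return ECGRecord(
        samples=mv,
        fs=fs,
        subject_id=record_name,
        lead_names=[s["name"] for s in sig_specs],
        record_id=record_name,
    )


def read_delimited_record(
    path: str | Path, fs: float, subject_id: str, delimiter: str = ","
) -> ECGRecord:
    """Read a plain numeric matrix (rows = samples, columns = leads)."""
    path = Path(path)
    if not path.exists() or not path.read_text().strip():
        raise ValueError(f"empty or missing signal file {path}")
    try:
        data = np.loadtxt(path, delimiter=delimiter, ndmin=2)
    except ValueError as exc:
        raise ValueError(f"non-numeric data in {path}: {exc}") from exc
    return ECGRecord(samples=data, fs=fs, subject_id=subject_id,
                     record_id=path.stem)


def read_cohort(cohort_dir: str | Path) -> LabeledCohort:
    """Read a cohort directory written by ``synthetic.write_cohort``."""
    cohort_dir = Path(cohort_dir)
    manifest = pd.read_csv(cohort_dir / "manifest.csv")
    records, split = [], []
    for row in manifest.itertuples():
        rec = read_delimited_record(cohort_dir / row.file, fs=row.fs,
                                    subject_id=row.subject_id)
        rec.record_id = row.record_id
        records.append(rec)
        split.append(row.split)
    return LabeledCohort(records=records, split_assignment=split)
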