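"""Minimal EDF / EDF+ reading and writing for simulated sessions.

Implements just enough of the European Data Format (16-bit EDF with an
"EDF Annotations" signal carrying task-onset events as EDF+ time-stamped
annotation lists) to round-trip :class:`~tfpbci.sim_eeg.Recording` objects.
Samples are quantized to 16 bits over a symmetric physical range, so the
round-trip error is bounded by ``physical_max / 2**15`` per sample.

The writer pads the last data record with zeros when the signal length is
not a whole number of records and stores the true sample count in the
header's reserved field (``NSAMP=<n>``), which the reader uses to trim the
padding.  Files written by other software without that hint simply keep the
padding.  Event annotations use the text ``<label>@<trial_id>``.
"""

from __future__ import annotations

import re
import warnings
from typing import BinaryIO

import numpy as np

from .errors import EdfError
from .sim_eeg import Event, Recording

__all__ = ["write_edf", "read_edf"]

_ANNOT_LABEL = "EDF Annotations"


def _fixed(text: str, width: int) -> bytes:
    """ASCII field of exactly ``width`` bytes, right-padded with spaces."""
    raw = text.encode("ascii")
    if len(raw) > width:
        raise EdfError(f"EDF header field {text!r} exceeds {width} bytes")
    return raw.ljust(width)


def _fmt_float(value: float, width: int = 8) -> str:
    """Shortest decimal representation of ``value`` fitting an EDF field."""
    for prec in range(6, -1, -1):
        s = f"{value:.{prec}f}".rstrip("0").rstrip(".")
        if len(s) <= width:
            return s or "0"
    raise EdfError(f"cannot format {value} in {width} chars")


def write_edf(
    rec: Recording,
    path,
    *,
    physical_max_uv: float | None = None,
    patient_id: str = "X X X X",
    recording_id: str = "Startdate 01-JAN-2020 X X tfpbci",
) -> None:
    """Write a recording as 16-bit EDF+ with event annotations.

    ``physical_max_uv`` sets the symmetric physical range; by default it is
    taken from the signal extremes so nothing clips.  If a caller-supplied
    range clips samples, a warning reports the clipped count.
    """
    fs = rec.fs_hz
    spr = int(round(fs))  # samples per 1-second record
    if abs(spr - fs) > 1e-9 or spr <= 0:
        raise EdfError(f"non-integer sampling rate {fs} Hz is not supported")

    n_ch, n_samp = rec.samples.shape
    n_records = max(1, int(np.ceil(n_samp / spr)))

    extreme = float(np.max(np.abs(rec.samples))) if rec.samples.size else 1.0
    if physical_max_uv is None:
        pmax = max(extreme * 1.001, 1e-6)
    else:
        pmax = float(physical_max_uv)
        if pmax <= 0:
            raise EdfError("physical_max_uv must be positive")
        if extreme > pmax:
            n_clip = int(np.sum(np.abs(rec.samples) > pmax))
            warnings.warn(
                f"{n_clip} samples exceed the physical range and will clip",
                stacklevel=2,
            )

    # quantize with exactly the gain/offset mapping the header declares:
    # physical [-pmax, pmax] <-> digital [-32768, 32767]
    pmax = float(_fmt_float(pmax))
    gain = 2 * pmax / 65535.0
    padded = np.zeros((n_ch, n_records * spr))
    padded[:, :n_samp] = rec.samples
    digital = np.clip(
        np.round((padded + pmax) / gain - 32768.0), -32768, 32767
    ).astype("<i2")

    # per-record annotation byte blocks (TALs)
    tals: list[bytes] = []
    ev_iter = iter(rec.events)
    ev = next(ev_iter, None)
    for r in range(n_records):
        block = f"+{r}\x14\x14\x00".encode("ascii")
        while ev is not None and ev.sample_index < (r + 1) * spr:
            onset = ev.sample_index / fs
            text = f"{ev.label}@{ev.trial_id}"
            block += f"+{onset:.6f}\x14{text}\x14\x00".encode("utf-8")
            ev = next(ev_iter, None)
        tals.append(block)
    annot_bytes = max(len(b) for b in tals)
    annot_bytes += annot_bytes % 2  # int16-sized signal
    annot_spr = annot_bytes // 2

    ns = n_ch + 1
    header = b"".join(
        [
            _fixed("0", 8),
            _fixed(patient_id, 80),
            _fixed(recording_id, 80),
            _fixed("01.01.20", 8),
            _fixed("00.00.00", 8),
            _fixed(str(256 * (ns + 1)), 8),
            _fixed(f"EDF+C NSAMP={n_samp}", 44),
            _fixed(str(n_records), 8),
            _fixed("1", 8),
            _fixed(str(ns), 4),
        ]
    )
    labels = [*(lab[:16] for lab in rec.channel_labels), _ANNOT_LABEL]
    phys_min = [_fmt_float(-pmax)] * n_ch + ["-1"]
    phys_max_f = [_fmt_float(pmax)] * n_ch + ["1"]
    dig_min = ["-32768"] * n_ch + ["-32768"]
    dig_max = ["32767"] * n_ch + ["32767"]
    sprs = [str(spr)] * n_ch + [str(annot_spr)]
    sig_header = b"".join(
        [
            b"".join(_fixed(lab, 16) for lab in labels),
            b"".join(_fixed("", 80) for _ in range(ns)),
            b"".join(_fixed("uV" if i < n_ch else "", 8) for i in range(ns)),
            b"".join(_fixed(v, 8) for v in phys_min),
            b"".join(_fixed(v, 8) for v in phys_max_f),
            b"".join(_fixed(v, 8) for v in dig_min),
            b"".join(_fixed(v, 8) for v in dig_max),
            b"".join(_fixed("", 80) for _ in range(ns)),
            b"".join(_fixed(v, 8) for v in sprs),
            b"".join(_fixed("", 32) for _ in range(ns)),
        ]
    )

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        for r in range(n_records):
            fh.write(digital[:, r * spr:(r + 1) * spr].tobytes())
            fh.write(tals[r].ljust(annot_bytes, b"\x00"))


def _read_exact(fh: BinaryIO, n: int, what: str) -> bytes:
    data = fh.read(n)
    if len(data) != n:
        raise EdfError(f"truncated EDF file while reading {what}")
    return data


_TAL_RE = re.compile(
    rb"(?P<onset>[+-][0-9.]+)(?:\x15(?P<dur>[0-9.]+))?\x14(?P<texts>[^\x00]*)\x00"
)


def read_edf(path) -> Recording:
    """Read a 16-bit EDF/EDF+ file back into a :class:`Recording`.

    Annotation signals are decoded into events; annotations whose text is
    not ``<label>@<trial_id>`` get a sequential trial id.  Truncated or
    malformed files raise :class:`~tfpbci.errors.EdfError`.
    """
    with open(path, "rb") as fh:
        head = _read_exact(fh, 256, "header")
        try:
            n_records = int(head[236:244].decode("ascii").strip())
            record_dur = float(head[244:252].decode("ascii").strip())
            ns = int(head[252:256].decode("ascii").strip())
        except ValueError as exc:
            raise EdfError("malformed EDF header") from exc
        if ns <= 0 or n_records < 0 or record_dur <= 0:
            raise EdfError("malformed EDF header (counts)")
        reserved = head[192:236].decode("ascii", "replace")
        m = re.search(r"NSAMP=(\d+)", reserved)
        true_nsamp = int(m.group(1)) if m else None

        sig = _read_exact(fh, 256 * ns, "signal headers")

        # field offsets within the signal-header block, in bytes summed over
        # all signals: label 16, transducer 80, dim 8, phys_min 8, phys_max 8,
        # dig_min 8, dig_max 8, prefilter 80, spr 8, reserved 32
        def block(start: int, width: int) -> list[str]:
            out = []
            for i in range(ns):
                a = start * ns + i * width
                out.append(sig[a:a + width].decode("ascii").strip())
            return out

        labels = block(0, 16)
        try:
            pmin = [float(v) for v in block(104, 8)]
            pmax = [float(v) for v in block(112, 8)]
            dmin = [float(v) for v in block(120, 8)]
            dmax = [float(v) for v in block(128, 8)]
            sprs = [int(v) for v in block(216, 8)]
        except ValueError as exc:
            raise EdfError("malformed EDF signal header") from exc
        if any(s <= 0 for s in sprs):
            raise EdfError("non-positive samples-per-record")

        data_chans = [i for i in range(ns) if labels[i] != _ANNOT_LABEL]
        annot_chans = [i for i in range(ns) if labels[i] == _ANNOT_LABEL]
        if not data_chans:
            raise EdfError("EDF file contains no data signals")
        fs = sprs[data_chans[0]] / record_dur
        if any(sprs[i] != sprs[data_chans[0]] for i in data_chans):
            raise EdfError("mixed sampling rates are not supported")

        rec_len = sum(sprs)
        raw = np.frombuffer(
            _read_exact(fh, 2 * rec_len * n_records, "data records"), dtype="<i2"
        ).reshape(n_records, rec_len)

    bounds = np.cumsum([0] + sprs)
    chunks = {i: raw[:, bounds[i]:bounds[i + 1]] for i in range(ns)}

    samples = np.empty((len(data_chans), n_records * sprs[data_chans[0]]))
    for row, i in enumerate(data_chans):
        dig = chunks[i].reshape(-1).astype(np.float64)
        gain = (pmax[i] - pmin[i]) / (dmax[i] - dmin[i])
        samples[row] = pmin[i] + gain * (dig - dmin[i])
    if true_nsamp is not None:
        samples = samples[:, :true_nsamp]

    events: list[Event] = []
    seq = 0
    for i in annot_chans:
        payload = chunks[i].reshape(-1).tobytes()
        for m_tal in _TAL_RE.finditer(payload):
            texts = [t for t in m_tal.group("texts").split(b"\x14") if t]
            onset = float(m_tal.group("onset"))
            for text in texts:
                s = text.decode("utf-8", "replace")
                if "@" in s:
                    label, _, tid = s.rpartition("@")
                    try:
                        trial_id = int(tid)
                    except ValueError:
                        label, trial_id = s, seq
                else:
                    label, trial_id = s, seq
                events.append(Event(int(round(onset * fs)), label, trial_id))
                seq += 1
    events.sort(key=lambda e: e.sample_index)

    return Recording(
        samples=samples,
        fs_hz=fs,
        channel_labels=tuple(labels[i] for i in data_chans),
        events=tuple(events),
    )
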