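"""EEG file I/O: plain TSV matrices and a minimal EDF reader/writer.

The TSV layout is channels x samples with a header row of channel labels
(one column per channel, transposed on read).  The EDF support covers the
plain (non-plus) continuous-recording subset of the format, which is all
this pipeline needs.
"""

from __future__ import annotations

import numpy as np

from .errors import FormatError
from .esi import EEGEpoch


def read_eeg_tsv(path, srate: float = None) -> EEGEpoch:
    """Read a TSV matrix (header row of labels, one column per channel).

    The sampling rate is taken from a ``# srate_hz=...`` comment on the
    first line when present, else from the ``srate`` argument.
    """
    with open(path) as fh:
        first = fh.readline().strip()
        if first.startswith("#"):
            for tok in first.lstrip("#").split():
                if tok.startswith("srate_hz="):
                    srate = float(tok.split("=", 1)[1])
            header = fh.readline().strip()
        else:
            header = first
        labels = header.split("\t")
        data = np.loadtxt(fh, delimiter="\t", ndmin=2)
    if srate is None:
        raise FormatError(f"{path}: no sampling rate in file; pass srate=")
    if data.shape[1] != len(labels):
        raise FormatError(
            f"{path}: {len(labels)} labels but {data.shape[1]} data columns"
        )
    return EEGEpoch(data.T, srate, labels)


def write_eeg_tsv(eeg: EEGEpoch, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# srate_hz={eeg.srate:g}\n")
        fh.write("\t".join(eeg.labels) + "\n")
        np.savetxt(fh, eeg.data.T, delimiter="\t", fmt="%.9g")


# ---------------------------------------------------------------------------
# EDF

def _f(x, n):  # fixed-width ASCII field
    s = f"{x}"[:n]
    return s.ljust(n).encode("ascii")


def write_edf(eeg: EEGEpoch, path, physical_range=None) -> None:
    """Write an epoch as a single-record EDF file (16-bit samples)."""
    m, t = eeg.data.shape
    if physical_range is None:
        amp = max(float(np.abs(eeg.data).max()), 1e-9)
        physical_range = (-amp, amp)
    pmin, pmax = physical_range
    dmin, dmax = -32768, 32767
    scale = (dmax - dmin) / (pmax - pmin)
    dig = np.round((eeg.data - pmin) * scale + dmin).astype("<i2")
    dur = t / eeg.srate
    with open(path, "wb") as fh:
        fh.write(_f("0", 8))
        fh.write(_f("X", 80))  # patient
        fh.write(_f("X", 80))  # recording
        fh.write(_f("01.01.00", 8))
        fh.write(_f("00.00.00", 8))
        fh.write(_f(256 + 256 * m, 8))
        fh.write(_f("", 44))
        fh.write(_f(1, 8))          # one data record
        fh.write(_f(f"{dur:.6g}", 8))
        fh.write(_f(m, 4))
        for lab in eeg.labels:
            fh.write(_f(lab, 16))
        for _ in range(m):
            fh.write(_f("", 80))    # transducer
        for _ in range(m):
            fh.write(_f("uV", 8))
        for lo in (pmin, pmax):
            for _ in range(m):
                fh.write(_f(f"{lo:.6g}", 8))
        for lo in (dmin, dmax):
            for _ in range(m):
                fh.write(_f(lo, 8))
        for _ in range(m):
            fh.write(_f("", 80))    # prefiltering
        for _ in range(m):
            fh.write(_f(t, 8))      # samples per record
        for _ in range(m):
            fh.write(_f("", 32))
        fh.write(dig.tobytes())     # channel-sequential within the record


def read_edf(path) -> EEGEpoch:
    """Read a continuous EDF recording into a single epoch (microvolts)."""
    with open(path, "rb") as fh:
        hdr = fh.read(256)
        if len(hdr) < 256:
            raise FormatError(f"{path}: truncated EDF header")
        n_rec = int(hdr[236:244].decode("ascii", "replace").strip() or -1)
        rec_dur = float(hdr[244:252].decode("ascii", "replace").strip() or 0)
        m = int(hdr[252:256].decode("ascii", "replace").strip())
        sig = fh.read(256 * m)
        if len(sig) < 256 * m:
            raise FormatError(f"{path}: truncated EDF signal headers")

        def field(off, width):
            base = off * m
            return [
                sig[base + i * width: base + (i + 1) * width]
                .decode("ascii", "replace").strip()
                for i in range(m)
            ]

        labels = field(0, 16)
        pmin = np.array([float(x) for x in field(104, 8)])
        pmax = np.array([float(x) for x in field(112, 8)])
        dmin = np.array([float(x) for x in field(120, 8)])
        dmax = np.array([float(x) for x in field(128, 8)])
        nsamp = np.array([int(x) for x in field(216, 8)])
        payload = fh.read()
    if n_rec < 0:
        n_rec = len(payload) // (2 * int(nsamp.sum()))
    if len(set(nsamp)) != 1:
        raise FormatError(f"{path}: per-channel sampling rates differ")
    t = int(nsamp[0])
    raw = np.frombuffer(payload, dtype="<i2", count=n_rec * m * t)
    raw = raw.reshape(n_rec, m, t)
    data = np.concatenate([raw[r] for r in range(n_rec)], axis=1).astype(float)
    gain = (pmax - pmin) / (dmax - dmin)
    data = (data - dmin[:, None]) * gain[:, None] + pmin[:, None]
    srate = t / rec_dur if rec_dur > 0 else 1.0
    return EEGEpoch(data, srate, labels)
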