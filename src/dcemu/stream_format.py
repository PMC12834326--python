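"""Bit-exact reader/writer for the EMU's hourly binary files.

The acquisition firmware emits a fixed 63-byte telemetry packet per sample
tick::

    counter(3, big-endian unsigned)
    status AFE1(3, opaque)
    AFE1 channels 1-8 (8 x 3 bytes, big-endian two's complement)
    status AFE2(3, opaque)
    AFE2 channels 1-8 (8 x 3 bytes, big-endian two's complement)
    acceleration x, y, z (3 x 2 bytes, little-endian two's complement)

Channel codes use the analog front end's native big-endian 24-bit order; the
accelerometer's native order is little-endian 16-bit.  The 3-byte packet
counter wraps modulo 2**24 and is audited by
:func:`check_counter_continuity` to find acquisition dropouts.

Hourly files are a 4096-byte header followed by a packet stream; the first
packet starts at byte offset 4096 (0-based).  The header dialect is UTF-8
``key=value`` lines zero-padded to exactly 4096 bytes, opening with a magic
line carrying the format version, so files are self-describing and
inspectable with a pager.  The two 3-byte AFE status words are carried
opaquely; their internal flag bits are not interpreted here.

Raw ADC codes convert to physical units as::

    volts = code * (vref / gain) / 2**23          (24-bit biopotential code)
    g     = code * full_scale_g / 2**15           (16-bit acceleration code)

which at gain 1 and vref 4.5 V gives the device's +-4.5 V dynamic range.
"""

from __future__ import annotations

import datetime
import io
import json
import os
import warnings
from dataclasses import dataclass, field
from typing import BinaryIO, Iterable, Iterator

import numpy as np

__all__ = [
    "PACKET_SIZE", "HEADER_SIZE", "N_CHANNELS", "COUNTER_MOD",
    "RawPacket", "RecordingHeader", "CounterGap", "TrailingFragmentWarning",
    "encode_packet", "decode_packet", "encode_packet_array",
    "decode_packet_array", "encode_header", "decode_header",
    "write_hourly_file", "read_hourly_file", "read_hourly_arrays",
    "code_to_volts", "volts_to_code", "accel_code_to_g", "g_to_accel_code",
    "check_counter_continuity", "hourly_filename", "channels_to_csv",
]

PACKET_SIZE = 63
HEADER_SIZE = 4096
N_CHANNELS = 16          # biopotential channels per packet (2 AFEs x 8)
COUNTER_MOD = 1 << 24    # 3-byte packet counter wraps here
_HEADER_MAGIC = "EMUHDR"

_CODE24_MIN, _CODE24_MAX = -(1 << 23), (1 << 23) - 1
_CODE16_MIN, _CODE16_MAX = -(1 << 15), (1 << 15) - 1


class TrailingFragmentWarning(UserWarning):
    """A file ended with a partial (< 63 byte) packet, e.g. after power loss."""


@dataclass(frozen=True)
class RawPacket:
    """One decoded 63-byte telemetry sample."""

    counter: int
    status_afe1: bytes = b"\x00\x00\x00"
    chan_codes_afe1: tuple = (0,) * 8
    status_afe2: bytes = b"\x00\x00\x00"
    chan_codes_afe2: tuple = (0,) * 8
    accel_codes: tuple = (0, 0, 0)

    def __post_init__(self):
        if not 0 <= self.counter < COUNTER_MOD:
            raise ValueError(f"counter {self.counter} outside [0, 2^24)")
        for name in ("status_afe1", "status_afe2"):
            if len(getattr(self, name)) != 3:
                raise ValueError(f"{name} must be exactly 3 bytes")
        for name in ("chan_codes_afe1", "chan_codes_afe2"):
            codes = tuple(getattr(self, name))
            object.__setattr__(self, name, codes)
            if len(codes) != 8:
                raise ValueError(f"{name} must hold 8 channel codes")
            for c in codes:
                if not _CODE24_MIN <= c <= _CODE24_MAX:
                    raise ValueError(f"{name} code {c} outside signed 24-bit range")
        accel = tuple(self.accel_codes)
        object.__setattr__(self, "accel_codes", accel)
        if len(accel) != 3:
            raise ValueError("accel_codes must hold 3 values (x, y, z)")
        for c in accel:
            if not _CODE16_MIN <= c <= _CODE16_MAX:
                raise ValueError(f"accel_codes value {c} outside signed 16-bit range")

    @property
    def chan_codes(self) -> tuple:
        """All 16 biopotential channel codes (AFE1 then AFE2)."""
        return self.chan_codes_afe1 + self.chan_codes_afe2


def encode_packet(p: RawPacket) -> bytes:
    """Serialize a packet to its exact 63-byte wire form."""
    out = bytearray()
    out += p.counter.to_bytes(3, "big")
    out += p.status_afe1
    for c in p.chan_codes_afe1:
        out += int(c).to_bytes(3, "big", signed=True)
    out += p.status_afe2
    for c in p.chan_codes_afe2:
        out += int(c).to_bytes(3, "big", signed=True)
    for c in p.accel_codes:
        out += int(c).to_bytes(2, "little", signed=True)
    assert len(out) == PACKET_SIZE
    return bytes(out)


def decode_packet(b: bytes) -> RawPacket:
    """Exact inverse of :func:`encode_packet`."""
    if len(b) != PACKET_SIZE:
        raise ValueError(f"packet must be exactly {PACKET_SIZE} bytes, got {len(b)}")
    counter = int.from_bytes(b[0:3], "big")
    status1 = bytes(b[3:6])
    afe1 = tuple(int.from_bytes(b[6 + 3 * i: 9 + 3 * i], "big", signed=True)
                 for i in range(8))
    status2 = bytes(b[30:33])
    afe2 = tuple(int.from_bytes(b[33 + 3 * i: 36 + 3 * i], "big", signed=True)
                 for i in range(8))
    accel = tuple(int.from_bytes(b[57 + 2 * i: 59 + 2 * i], "little", signed=True)
                  for i in range(3))
    return RawPacket(counter, status1, afe1, status2, afe2, accel)


def encode_packet_array(counters: np.ndarray, chan_codes: np.ndarray,
                        accel_codes: np.ndarray,
                        status_afe1: np.ndarray | None = None,
                        status_afe2: np.ndarray | None = None) -> bytes:
    """Vectorised packet serialisation for whole streams.

    Parameters
    ----------
    counters : (n,) integer array, values in [0, 2**24)
    chan_codes : (n, 16) signed 24-bit codes (AFE1 channels 0-7, AFE2 8-15)
    accel_codes : (n, 3) signed 16-bit codes
    status_afe1, status_afe2 : optional (n, 3) uint8 arrays; default zeros

    Byte-identical to concatenating :func:`encode_packet` over the stream.
    """
    counters = np.asarray(counters)
    chan_codes = np.asarray(chan_codes)
    accel_codes = np.asarray(accel_codes)
    n = len(counters)
    if chan_codes.shape != (n, N_CHANNELS):
        raise ValueError(f"chan_codes must have shape ({n}, {N_CHANNELS})")
    if accel_codes.shape != (n, 3):
        raise ValueError(f"accel_codes must have shape ({n}, 3)")
    if np.any((counters < 0) | (counters >= COUNTER_MOD)):
        raise ValueError("counter outside [0, 2^24)")
    if np.any((chan_codes < _CODE24_MIN) | (chan_codes > _CODE24_MAX)):
        raise ValueError("channel code outside signed 24-bit range")
    if np.any((accel_codes < _CODE16_MIN) | (accel_codes > _CODE16_MAX)):
        raise ValueError("acceleration code outside signed 16-bit range")

    buf = np.zeros((n, PACKET_SIZE), dtype=np.uint8)
    # 3 low bytes of a big-endian uint32 are the 3-byte big-endian counter
    buf[:, 0:3] = counters.astype(">u4").view(np.uint8).reshape(n, 4)[:, 1:]
    if status_afe1 is not None:
        buf[:, 3:6] = status_afe1
    if status_afe2 is not None:
        buf[:, 30:33] = status_afe2
    # low 3 bytes of big-endian int32 == 24-bit two's complement for in-range values
    code_bytes = chan_codes.astype(">i4").view(np.uint8).reshape(n, N_CHANNELS, 4)[:, :, 1:]
    buf[:, 6:30] = code_bytes[:, :8].reshape(n, 24)
    buf[:, 33:57] = code_bytes[:, 8:].reshape(n, 24)
    buf[:, 57:63] = accel_codes.astype("<i2").view(np.uint8).reshape(n, 6)
    return buf.tobytes()


def decode_packet_array(data: bytes) -> dict:
    """Vectorised inverse of :func:`encode_packet_array`.

    Returns a dict with ``counters`` (n,), ``chan_codes`` (n, 16) int32,
    ``accel_codes`` (n, 3) int16, ``status_afe1``/``status_afe2`` (n, 3) uint8
    and ``fragment_bytes`` (length of any trailing partial packet).
    """
    raw = np.frombuffer(data, dtype=np.uint8)
    n, frag = divmod(len(raw), PACKET_SIZE)
    buf = raw[: n * PACKET_SIZE].reshape(n, PACKET_SIZE)
    counters = (buf[:, 0].astype(np.int64) << 16) | (buf[:, 1].astype(np.int64) << 8) \
        | buf[:, 2].astype(np.int64)
    code_bytes = np.concatenate([buf[:, 6:30], buf[:, 33:57]], axis=1)
    code_bytes = code_bytes.reshape(n, N_CHANNELS, 3).astype(np.int64)
    codes = (code_bytes[:, :, 0] << 16) | (code_bytes[:, :, 1] << 8) | code_bytes[:, :, 2]
    codes[codes >= (1 << 23)] -= 1 << 24
    accel = buf[:, 57:63].copy().view("<i2").reshape(n, 3)
    return {
        "counters": counters,
        "chan_codes": codes.astype(np.int32),
        "accel_codes": accel.astype(np.int16),
        "status_afe1": buf[:, 3:6].copy(),
        "status_afe2": buf[:, 30:33].copy(),
        "fragment_bytes": frag,
    }


@dataclass
class RecordingHeader:
    """Device configuration stored in the first 4096 bytes of an hourly file."""

    format_version: int = 1
    start_time_utc: float = 0.0
    sample_rate_hz: float = 1000.0
    afe_gain: tuple = (1.0, 1.0)
    vref_volts: float = 4.5
    accel_full_scale_g: float = 2.0
    channel_labels: tuple = (
        "HAL", "HAR", "HPL", "HPR", "HVL", "HVR", "EFL", "EFR",
        "EAL", "EAR", "EPL", "EPR", "ECG", "CPA", "AUX1", "AUX2",
    )
    dac_waveform: dict | None = None
    rig_id: str = "rig00"

    def __post_init__(self):
        self.afe_gain = tuple(float(g) for g in self.afe_gain)
        self.channel_labels = tuple(self.channel_labels)
        if len(self.channel_labels) != N_CHANNELS:
            raise ValueError(f"need exactly {N_CHANNELS} channel labels")
        if len(set(self.channel_labels)) != N_CHANNELS:
            raise ValueError("channel labels must be unique")
        if not self.sample_rate_hz > 0:
            raise ValueError("sample_rate_hz must be positive")
        for g in self.afe_gain:
            if not g > 0:
                raise ValueError("AFE gains must be positive")
        if not self.vref_volts > 0:
            raise ValueError("vref_volts must be positive")
        if not self.accel_full_scale_g > 0:
            raise ValueError("accel_full_scale_g must be positive")

    def gain_for_channel(self, index: int) -> float:
        """AFE gain applying to biopotential channel ``index`` (0-15)."""
        return self.afe_gain[0] if index < 8 else self.afe_gain[1]


def encode_header(h: RecordingHeader) -> bytes:
    """Serialize a header to exactly 4096 zero-padded UTF-8 bytes."""
    lines = [
        f"{_HEADER_MAGIC} format_version={h.format_version}",
        f"rig_id={h.rig_id}",
        f"start_time_utc={h.start_time_utc!r}",
        f"sample_rate_hz={h.sample_rate_hz!r}",
        f"afe_gain={h.afe_gain[0]!r},{h.afe_gain[1]!r}",
        f"vref_volts={h.vref_volts!r}",
        f"accel_full_scale_g={h.accel_full_scale_g!r}",
        "channel_labels=" + ",".join(h.channel_labels),
    ]
    if h.dac_waveform is not None:
        lines.append("dac_waveform=" + json.dumps(h.dac_waveform, separators=(",", ":")))
    blob = ("\n".join(lines) + "\n").encode("utf-8")
    if len(blob) > HEADER_SIZE:
        raise ValueError(f"header does not fit in {HEADER_SIZE} bytes")
    return blob + b"\x00" * (HEADER_SIZE - len(blob))


def decode_header(b: bytes) -> RecordingHeader:
    if len(b) < HEADER_SIZE:
        raise ValueError(f"header must be {HEADER_SIZE} bytes, got {len(b)}")
    text = b[:HEADER_SIZE].split(b"\x00", 1)[0].decode("utf-8")
    lines = [ln for ln in text.splitlines() if ln]
    if not lines or not lines[0].startswith(_HEADER_MAGIC + " "):
        raise ValueError("not an EMU header (magic string missing)")
    fields: dict = {}
    fields["format_version"] = int(lines[0].split("format_version=")[1])
    for ln in lines[1:]:
        key, _, val = ln.partition("=")
        fields[key] = val
    gains = tuple(float(g) for g in fields["afe_gain"].split(","))
    wf = json.loads(fields["dac_waveform"]) if "dac_waveform" in fields else None
    return RecordingHeader(
        format_version=fields["format_version"],
        start_time_utc=float(fields["start_time_utc"]),
        sample_rate_hz=float(fields["sample_rate_hz"]),
        afe_gain=gains,
        vref_volts=float(fields["vref_volts"]),
        accel_full_scale_g=float(fields["accel_full_scale_g"]),
        channel_labels=tuple(fields["channel_labels"].split(",")),
        dac_waveform=wf,
        rig_id=fields["rig_id"],
    )


def _as_sink(sink) -> tuple[BinaryIO, bool]:
    if hasattr(sink, "write"):
        return sink, False
    return open(sink, "wb"), True


def write_hourly_file(h: RecordingHeader, packets: Iterable[RawPacket], sink) -> int:
    """Write header + packet stream; returns total bytes written.

    Enforces the one-hour rotation boundary: at most ``fs * 3600`` packets
    belong in one file.  ``sink`` may be a path or a binary file object.
    """
    max_packets = int(h.sample_rate_hz * 3600)
    fh, close = _as_sink(sink)
    written = 0
    try:
        fh.write(encode_header(h))
        written += HEADER_SIZE
        count = 0
        for p in packets:
            count += 1
            if count > max_packets:
                raise ValueError(
                    f"packet count exceeds one-hour rotation boundary "
                    f"({max_packets} at {h.sample_rate_hz} Hz); "
                    f"{written} bytes written so far")
            fh.write(encode_packet(p))
            written += PACKET_SIZE
    finally:
        if close:
            fh.close()
    return written


def read_hourly_file(source) -> tuple[RecordingHeader, Iterator[RawPacket]]:
    """Read an hourly file: (header, lazy packet stream).

    A trailing partial packet (e.g. power loss mid-write) is surfaced as a
    :class:`TrailingFragmentWarning` carrying the byte count — never silently
    dropped.
    """
    if hasattr(source, "read"):
        data = source.read()
    else:
        with open(source, "rb") as fh:
            data = fh.read()
    if len(data) < HEADER_SIZE:
        raise ValueError(f"source shorter than the {HEADER_SIZE}-byte header "
                         f"({len(data)} bytes)")
    header = decode_header(data[:HEADER_SIZE])
    body = data[HEADER_SIZE:]

    def _packets() -> Iterator[RawPacket]:
        n, frag = divmod(len(body), PACKET_SIZE)
        for i in range(n):
            yield decode_packet(body[i * PACKET_SIZE:(i + 1) * PACKET_SIZE])
        if frag:
            warnings.warn(
                f"trailing partial packet of {frag} bytes ignored after "
                f"{n} complete packets", TrailingFragmentWarning)

    return header, _packets()


def read_hourly_arrays(source) -> tuple[RecordingHeader, dict]:
    """Like :func:`read_hourly_file` but decoding the body vectorised.

    Returns ``(header, arrays)`` with the :func:`decode_packet_array` dict;
    emits the same trailing-fragment warning.
    """
    if hasattr(source, "read"):
        data = source.read()
    else:
        with open(source, "rb") as fh:
            data = fh.read()
    if len(data) < HEADER_SIZE:
        raise ValueError(f"source shorter than the {HEADER_SIZE}-byte header")
    header = decode_header(data[:HEADER_SIZE])
    arrays = decode_packet_array(data[HEADER_SIZE:])
    if arrays["fragment_bytes"]:
        warnings.warn(
            f"trailing partial packet of {arrays['fragment_bytes']} bytes "
            f"ignored", TrailingFragmentWarning)
    return header, arrays


# ---------------------------------------------------------------------------
# raw-code <-> physical-unit conversion

def code_to_volts(code, gain: float, vref_volts: float):
    """ADC code -> volts: ``code * (vref/gain) / 2**23``.

    Strictly monotone and linear in ``code``; at gain 1, vref 4.5 the
    representable range spans the device's +-4.5 V dynamic range.
    """
    if not gain > 0:
        raise ValueError("gain must be positive")
    if not vref_volts > 0:
        raise ValueError("vref_volts must be positive")
    return np.asarray(code, dtype=np.float64) * (vref_volts / gain) / (1 << 23)


def volts_to_code(volts, gain: float, vref_volts: float) -> np.ndarray:
    """Inverse scaling with round-to-nearest and saturation to 24-bit range."""
    if not gain > 0:
        raise ValueError("gain must be positive")
    if not vref_volts > 0:
        raise ValueError("vref_volts must be positive")
    code = np.rint(np.asarray(volts, dtype=np.float64) * gain / vref_volts * (1 << 23))
    return np.clip(code, _CODE24_MIN, _CODE24_MAX).astype(np.int32)


def accel_code_to_g(code, full_scale_g: float):
    """Accelerometer code -> g: ``code * full_scale_g / 2**15`` (odd-symmetric)."""
    if not full_scale_g > 0:
        raise ValueError("full_scale_g must be positive")
    return np.asarray(code, dtype=np.float64) * full_scale_g / (1 << 15)


def g_to_accel_code(g, full_scale_g: float) -> np.ndarray:
    if not full_scale_g > 0:
        raise ValueError("full_scale_g must be positive")
    code = np.rint(np.asarray(g, dtype=np.float64) / full_scale_g * (1 << 15))
    return np.clip(code, _CODE16_MIN, _CODE16_MAX).astype(np.int16)


@dataclass(frozen=True)
class CounterGap:
    """A discontinuity in the packet counter stream."""

    position: int   # index of the first packet after the gap
    missing: int    # number of packets lost


def check_counter_continuity(packets) -> list:
    """Audit a packet stream for dropouts via the 3-byte counter.

    Accepts RawPacket objects or bare counter integers.  Returns an empty
    list iff counters advance by exactly 1 mod 2**24 throughout; the natural
    wrap 2**24-1 -> 0 is not a gap.
    """
    counters = np.asarray(
        [p.counter if isinstance(p, RawPacket) else int(p) for p in packets],
        dtype=np.int64)
    if len(counters) < 2:
        return []
    step = np.mod(np.diff(counters) - 1, COUNTER_MOD)
    gaps = np.flatnonzero(step != 0)
    return [CounterGap(position=int(i) + 1, missing=int(step[i])) for i in gaps]


def hourly_filename(rig_id: str, start_time_utc: float) -> str:
    """``<rig_id>_<ISO8601 start>.emu`` — file names carry the data start time."""
    ts = datetime.datetime.fromtimestamp(start_time_utc, tz=datetime.timezone.utc)
    return f"{rig_id}_{ts.strftime('%Y%m%dT%H%M%S')}.emu"


def channels_to_csv(header: RecordingHeader, arrays: dict, path) -> None:
    """Export decoded channels to CSV: time column (s) + one column per channel
    in volts + acceleration in g."""
    import pandas as pd

    codes = arrays["chan_codes"]
    n = len(codes)
    cols = {"time_s": np.arange(n) / header.sample_rate_hz}
    for i, label in enumerate(header.channel_labels):
        cols[label] = code_to_volts(codes[:, i], header.gain_for_channel(i),
                                    header.vref_volts)
    for j, axis in enumerate("xyz"):
        cols[f"acc_{axis}_g"] = accel_code_to_g(arrays["accel_codes"][:, j],
                                                header.accel_full_scale_g)
    pd.DataFrame(cols).to_csv(path, index=False)
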