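"""Minimal Standard MIDI File I/O for monophonic note sequences.

Writes format-0 files at 480 ticks per beat with a tempo meta-event,
and reads them back to a note table; phrase-boundary annotations travel
in a CSV sidecar (see :func:`write_boundary_sidecar`), not inside the
MIDI stream. Only the events this package emits are interpreted on
read (note on/off, tempo); other events are skipped. Reading a file
with overlapping notes -- polyphony -- is an error, reported with the
time of the first overlap.
"""

from __future__ import annotations

import struct
from pathlib import Path
from typing import Optional

import pandas as pd

from .melody import DEFAULT_TEMPO_BPM, NoteEvent, NoteSequence, PhraseStructure

TICKS_PER_BEAT = 480


def _vlq(value: int) -> bytes:
    """Encode a variable-length quantity."""
    out = [value & 0x7F]
    value >>= 7
    while value:
        out.append(0x80 | (value & 0x7F))
        value >>= 7
    return bytes(reversed(out))


def _read_vlq(data: bytes, pos: int):
    value = 0
    while True:
        b = data[pos]
        pos += 1
        value = (value << 7) | (b & 0x7F)
        if not b & 0x80:
            return value, pos


def write_midi(seq: NoteSequence, path) -> None:
    """Write a monophonic note sequence as a format-0 SMF."""
    if not seq.notes:
        raise ValueError("cannot write an empty note sequence")
    tempo = seq.structure.tempo_bpm if seq.structure is not None else DEFAULT_TEMPO_BPM
    events = []  # (tick, order, message bytes)
    us_per_beat = int(round(60_000_000 / tempo))
    events.append((0, 0, b"\xff\x51\x03" + us_per_beat.to_bytes(3, "big")))
    for n in seq.notes:
        pitch = int(round(n.pitch))
        if not 0 <= pitch <= 127:
            raise ValueError(f"pitch {n.pitch} outside MIDI range 0-127")
        on = int(round(n.onset_beats * TICKS_PER_BEAT))
        off = int(round((n.onset_beats + n.duration_beats) * TICKS_PER_BEAT))
        events.append((on, 2, bytes([0x90, pitch, 80])))
        events.append((off, 1, bytes([0x80, pitch, 0])))
    events.sort(key=lambda e: (e[0], e[1]))

    track = bytearray()
    last = 0
    for tick, _, msg in events:
        track += _vlq(tick - last) + msg
        last = tick
    track += _vlq(0) + b"\xff\x2f\x00"  # end of track

    with open(path, "wb") as fh:
        fh.write(b"MThd" + struct.pack(">IHHH", 6, 0, 1, TICKS_PER_BEAT))
        fh.write(b"MTrk" + struct.pack(">I", len(track)) + bytes(track))


def read_midi(path, structure: Optional[PhraseStructure] = None) -> NoteSequence:
    """Read a monophonic SMF back into a NoteSequence.

    Boundary annotations are not stored in MIDI; pass ``structure`` (or
    attach boundaries from the sidecar) to restore them.
    """
    data = Path(path).read_bytes()
    if data[:4] != b"MThd":
        raise ValueError(f"{path}: not a standard MIDI file")
    hlen, fmt, ntrk, division = struct.unpack(">IHHH", data[4:14])
    if division & 0x8000:
        raise ValueError("SMPTE time division is not supported")
    pos = 8 + hlen
    tempo_bpm = DEFAULT_TEMPO_BPM
    notes = []
    active = None  # (pitch, onset_tick)
    for _ in range(ntrk):
        if data[pos : pos + 4] != b"MTrk":
            raise ValueError(f"{path}: malformed track chunk")
        tlen = struct.unpack(">I", data[pos + 4 : pos + 8])[0]
        body = data[pos + 8 : pos + 8 + tlen]
        pos += 8 + tlen
        tick = 0
        p = 0
        status = 0
        while p < len(body):
            delta, p = _read_vlq(body, p)
            tick += delta
            b0 = body[p]
            if b0 >= 0x80:
                status = b0
                p += 1
            if status == 0xFF:  # meta
                mtype = body[p]
                mlen, p2 = _read_vlq(body, p + 1)
                payload = body[p2 : p2 + mlen]
                p = p2 + mlen
                if mtype == 0x51:
                    tempo_bpm = 60_000_000 / int.from_bytes(payload, "big")
                continue
            if status in (0xF0, 0xF7):  # sysex
                mlen, p2 = _read_vlq(body, p)
                p = p2 + mlen
                continue
            kind = status & 0xF0
            nbytes = 1 if kind in (0xC0, 0xD0) else 2
            args = body[p : p + nbytes]
            p += nbytes
            is_on = kind == 0x90 and args[1] > 0
            is_off = kind == 0x80 or (kind == 0x90 and args[1] == 0)
            if is_on:
                if active is not None:
                    t_s = tick / division * 60.0 / tempo_bpm
                    raise ValueError(
                        f"{path}: polyphonic overlap at tick {tick} "
                        f"({t_s:.3f} s): note {args[0]} starts while "
                        f"note {active[0]} is sounding"
                    )
                active = (args[0], tick)
            elif is_off:
                if active is None or active[0] != args[0]:
                    continue
                on_pitch, on_tick = active
                notes.append(
                    NoteEvent(on_tick / division, (tick - on_tick) / division, float(on_pitch))
                )
                active = None
    if not notes:
        raise ValueError(f"{path}: no notes found")
    boundaries = tuple(structure.boundary_beats) if structure is not None else ()
    return NoteSequence(tuple(notes), structure, boundaries)


def write_boundary_sidecar(seq: NoteSequence, path, melody_id: Optional[str] = None) -> None:
    """CSV sidecar: melody_id, boundary_index, beat, seconds."""
    tempo = seq.structure.tempo_bpm if seq.structure is not None else DEFAULT_TEMPO_BPM
    rows = [
        {
            "melody_id": melody_id if melody_id is not None else seq.melody_id,
            "boundary_index": i,
            "beat": b,
            "seconds": b * 60.0 / tempo,
        }
        for i, b in enumerate(seq.boundaries_beats)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_boundary_sidecar(path) -> pd.DataFrame:
    return pd.read_csv(path)
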