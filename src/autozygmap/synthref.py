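"""Deterministic synthetic reference genome with O(1) random access.

Bases are generated positionally from a 64-bit mixing function of
(seed, chromosome, position), so any window — or the full FASTA — can be
materialised on demand without storing the genome.  Gene coding sequences
are laid over the background as explicit patches (drawn from non-stop
codons by the genome builder), keeping every access path, including FASTA
export, byte-for-byte reproducible for a given seed.

This module produces synthetic stand-in sequence for testing and
simulation; it makes no attempt to mimic real genome composition beyond
uniform base usage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = {65: 0, 67: 1, 71: 2, 84: 3}  # A C G T


def _mix64(x: np.ndarray) -> np.ndarray:
    """splitmix64 finaliser; input/output uint64 arrays (wrapping arithmetic)."""
    x = (x + np.uint64(0x9E3779B97F4A7C15))
    x ^= x >> np.uint64(30)
    x *= np.uint64(0xBF58476D1CE4E5B9)
    x ^= x >> np.uint64(27)
    x *= np.uint64(0x94D049BB133111EB)
    x ^= x >> np.uint64(31)
    return x


def seq_to_codes(seq: str) -> np.ndarray:
    raw = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.empty(len(raw), dtype=np.uint8)
    for byte, code in _CODE.items():
        out[raw == byte] = code
    return out


def codes_to_seq(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


@dataclass
class SyntheticReference:
    """Positionally-generated genome with sequence overlays."""

    chromosomes: list[tuple[str, int]]
    seed: int
    _overlays: dict[str, list[tuple[int, np.ndarray]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._index = {name: i for i, (name, _len) in enumerate(self.chromosomes)}
        self._length = dict(self.chromosomes)

    def length(self, chrom: str) -> int:
        return self._length[chrom]

    def add_overlay(self, chrom: str, start0: int, seq: str) -> None:
        """Patch ``seq`` onto the background at ``start0`` (0-based)."""
        self._overlays.setdefault(chrom, []).append((start0, seq_to_codes(seq)))
        self._overlays[chrom].sort(key=lambda t: t[0])

    def _background(self, chrom: str, positions0: np.ndarray) -> np.ndarray:
        salt = _mix64(np.array([self.seed * 0x10001 + self._index[chrom]], dtype=np.uint64))[0]
        h = _mix64(positions0.astype(np.uint64) ^ salt)
        return (h & np.uint64(3)).astype(np.uint8)

    def base_codes_at(self, chrom: str, positions0: np.ndarray) -> np.ndarray:
        """Base codes (0..3 = ACGT) at scattered 0-based positions."""
        positions0 = np.asarray(positions0, dtype=np.int64)
        codes = self._background(chrom, positions0)
        for start, patch in self._overlays.get(chrom, []):
            inside = (positions0 >= start) & (positions0 < start + len(patch))
            if inside.any():
                codes[inside] = patch[positions0[inside] - start]
        return codes

    def fetch(self, chrom: str, start0: int, end0: int) -> str:
        """Sequence of ``[start0, end0)`` as an ACGT string."""
        if not 0 <= start0 <= end0 <= self._length[chrom]:
            raise ValueError(f"window [{start0},{end0}) outside {chrom}")
        return codes_to_seq(self.base_codes_at(chrom, np.arange(start0, end0)))

    def write_fasta(self, path, line_len: int = 60, window: int = 1_000_000) -> None:
        with open(path, "w") as fh:
            for name, length in self.chromosomes:
                fh.write(f">{name}\n")
                buf = ""
                for s in range(0, length, window):
                    buf += self.fetch(name, s, min(length, s + window))
                    while len(buf) >= line_len:
                        fh.write(buf[:line_len] + "\n")
                        buf = buf[line_len:]
                if buf:
                    fh.write(buf + "\n")
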