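"""Cumulated-phase signal encoding of DNA strings.

Each base maps to a complex number (A: 1+j, C: -1-j, G: -1+j, T: 1-j); the
signal is the running sum of the complex arguments.  The arguments are exact
multiples of pi/4, so increments are accumulated as small integers and
multiplied by pi/4 once, keeping signals bit-reproducible.
"""

from __future__ import annotations

import numpy as np

#: complex-argument of each base's mapping, in units of pi/4
PHASE_QUARTERS = {"A": 1, "C": -3, "G": 3, "T": -1}

_LUT = np.full(256, 127, dtype=np.int8)
for _b, _q in PHASE_QUARTERS.items():
    _LUT[ord(_b)] = _q
    _LUT[ord(_b.lower())] = _q


class EncodingError(ValueError):
    """Raised when a sequence contains a symbol outside {A,C,G,T}."""


def phase_increments(sequence: str) -> np.ndarray:
    """Per-base phase increments (radians); each is +-pi/4 or +-3pi/4."""
    return _quarter_increments(sequence) * (np.pi / 4.0)


def _quarter_increments(sequence: str) -> np.ndarray:
    if not sequence:
        raise EncodingError("cannot encode an empty sequence")
    codes = np.frombuffer(sequence.encode("ascii", errors="replace"), dtype=np.uint8)
    quarters = _LUT[codes]
    bad = np.nonzero(quarters == 127)[0]
    if bad.size:
        pos = int(bad[0])
        raise EncodingError(f"illegal symbol {sequence[pos]!r} at position {pos}")
    return quarters.astype(np.int64)


def encode_cumulated_phase(sequence: str) -> np.ndarray:
    """Encode a DNA string as its cumulated-phase signal.

    Parameters
    ----------
    sequence : str
        Non-empty string over {A,C,G,T} (case-insensitive).

    Returns
    -------
    numpy.ndarray
        Float array of the same length; entry ``k`` is the sum of the
        complex arguments of the first ``k+1`` mapped bases.
    """
    return np.cumsum(_quarter_increments(sequence)) * (np.pi / 4.0)


def signals_to_tsv(signals: dict[str, np.ndarray], path) -> None:
    """Dump named signals as a sparse two-column-per-signal TSV for inspection."""
    with open(path, "w") as fh:
        for name, sig in signals.items():
            values = "\t".join(f"{v:.10g}" for v in sig)
            fh.write(f"{name}\t{values}\n")
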