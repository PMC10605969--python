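"""Fixed six-letter alphabet of the pan-genome text.

The text concatenates the input sequences with ``%`` separators and a final
``$`` sentinel.  The ordering ``$ < % < A < C < G < T`` is load-bearing: the
sentinel must be the smallest character and the separator the second smallest,
so that all suffixes starting at a separator occupy the first rows of the
suffix array (one row per sequence end).
"""

from __future__ import annotations

import numpy as np

SIGMA = "$%ACGT"
SENTINEL = "$"
SEPARATOR = "%"
DNA = "ACGT"

#: number of characters in the alphabet
SIGMA_SIZE = len(SIGMA)

CODE = {c: i for i, c in enumerate(SIGMA)}
DNA_CODES = tuple(CODE[c] for c in DNA)
SEP_CODES = (CODE[SENTINEL], CODE[SEPARATOR])

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# byte value -> code, 255 for anything outside the alphabet
_ENC = np.full(256, 255, dtype=np.uint8)
for _c, _i in CODE.items():
    _ENC[ord(_c)] = _i
_DEC = np.frombuffer(SIGMA.encode(), dtype=np.uint8)


class AlphabetError(ValueError):
    """A character outside ``$%ACGT`` was encountered."""


def encode(s: str) -> np.ndarray:
    """Encode a string over the alphabet into a uint8 code array.

    Raises :class:`AlphabetError` naming the first offending position.
    """
    raw = np.frombuffer(s.encode("ascii", errors="replace"), dtype=np.uint8)
    codes = _ENC[raw]
    bad = np.flatnonzero(codes == 255)
    if bad.size:
        pos = int(bad[0])
        raise AlphabetError(
            f"character {s[pos]!r} at position {pos} is outside alphabet {SIGMA!r}"
        )
    return codes


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode`."""
    return _DEC[np.asarray(codes, dtype=np.uint8)].tobytes().decode("ascii")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a plain A/C/G/T string."""
    return seq.translate(_COMPLEMENT)[::-1]


def is_separator(ch: str) -> bool:
    return ch in (SENTINEL, SEPARATOR)
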