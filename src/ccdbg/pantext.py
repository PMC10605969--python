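"""The concatenated pan-genome text and its per-sequence bookkeeping."""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from bisect import bisect_right
from typing import Iterable, Sequence

import numpy as np

from .alphabet import DNA, SENTINEL, SEPARATOR, encode


class InputError(ValueError):
    """Invalid pan-genome input."""


@dataclass
class PanGenomeText:
    """Concatenation of ``S`` DNA sequences, ``%``-separated, ``$``-terminated.

    Zero-based, half-open coordinates throughout.  ``seq_starts[s]`` is the
    global position of the first character of sequence ``s``; the character at
    ``seq_starts[s] + len(seq s)`` is its separator (``%`` for all but the last
    sequence, ``$`` for the last).
    """

    T: str
    seq_names: list[str]
    seq_starts: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.n = len(self.T)
        self.S = len(self.seq_names)
        if not self.seq_starts:
            raise InputError("seq_starts must be provided (use from_sequences)")
        self.validate()
        self.codes = encode(self.T)

    # ------------------------------------------------------------------
    @classmethod
    def from_sequences(
        cls,
        seqs: Sequence[str],
        names: Iterable[str] | None = None,
        n_replacement_seed: int | None = None,
    ) -> "PanGenomeText":
        """Build the text from raw A/C/G/T sequences.

        ``N`` bases are replaced by a seeded pseudo-random nucleotide when
        ``n_replacement_seed`` is given (an error otherwise), mirroring common
        practice for FM-indexed references with a 4-letter DNA alphabet.
        """
        seqs = [s.upper() for s in seqs]
        if not seqs:
            raise InputError("at least one sequence is required")
        if names is None:
            names = [f"seq{i}" for i in range(len(seqs))]
        names = list(names)
        if len(names) != len(seqs):
            raise InputError("number of names must match number of sequences")
        rng = None
        cleaned = []
        for si, s in enumerate(seqs):
            if "N" in s:
                if n_replacement_seed is None:
                    raise InputError(
                        f"sequence {names[si]!r} contains 'N'; "
                        "pass n_replacement_seed to replace them"
                    )
                if rng is None:
                    rng = np.random.default_rng(n_replacement_seed)
                chars = list(s)
                for i, c in enumerate(chars):
                    if c == "N":
                        chars[i] = DNA[rng.integers(4)]
                s = "".join(chars)
            bad = set(s) - set(DNA)
            if bad:
                raise InputError(
                    f"sequence {names[si]!r} contains non-ACGT characters {sorted(bad)}"
                )
            if not s:
                raise InputError(f"sequence {names[si]!r} is empty")
            cleaned.append(s)
        starts, pos = [], 0
        for s in cleaned:
            starts.append(pos)
            pos += len(s) + 1  # body + separator/sentinel
        text = SEPARATOR.join(cleaned) + SENTINEL
        return cls(T=text, seq_names=names, seq_starts=starts)

    @classmethod
    def from_fasta(
        cls, path_or_handle, n_replacement_seed: int | None = None
    ) -> "PanGenomeText":
        """Read a multi-FASTA file; record order defines sequence indices."""
        if isinstance(path_or_handle, (str, bytes)) or hasattr(path_or_handle, "__fspath__"):
            handle = open(path_or_handle)
            close = True
        else:
            handle, close = path_or_handle, False
        names: list[str] = []
        seqs: list[str] = []
        try:
            buf: list[str] = []
            for line in handle:
                line = line.strip()
                if not line:
                    continue
                if line.startswith(">"):
                    if names:
                        seqs.append("".join(buf))
                    names.append(line[1:].split()[0])
                    buf = []
                else:
                    buf.append(line)
            if names:
                seqs.append("".join(buf))
        finally:
            if close:
                handle.close()
        if not names:
            raise InputError("no FASTA records found")
        return cls.from_sequences(seqs, names, n_replacement_seed=n_replacement_seed)

    # ------------------------------------------------------------------
    def validate(self) -> None:
        if not self.T.endswith(SENTINEL) or self.T.count(SENTINEL) != 1:
            raise InputError("text must end with exactly one '$'")
        if self.T.count(SEPARATOR) != self.S - 1:
            raise InputError("text must contain exactly S-1 '%' separators")
        if self.seq_starts[0] != 0:
            raise InputError("first sequence must start at position 0")
        for s in range(self.S):
            end = self.seq_end(s)
            body = self.T[self.seq_starts[s] : end]
            if any(c not in DNA for c in body):
                raise InputError(f"sequence {s} body contains non-ACGT characters")
            sep = self.T[end]
            want = SENTINEL if s == self.S - 1 else SEPARATOR
            if sep != want:
                raise InputError(f"sequence {s} is not terminated by {want!r}")

    # ------------------------------------------------------------------
    def seq_end(self, s: int) -> int:
        """Global position of the separator that terminates sequence ``s``."""
        if s == self.S - 1:
            return self.n - 1
        return self.seq_starts[s + 1] - 1

    def seq_length(self, s: int) -> int:
        return self.seq_end(s) - self.seq_starts[s]

    def sequence(self, s: int) -> str:
        return self.T[self.seq_starts[s] : self.seq_end(s)]

    def seq_of(self, global_pos: int) -> int:
        """Largest ``s`` with ``seq_starts[s] <= global_pos``."""
        return bisect_right(self.seq_starts, global_pos) - 1

    def separator_positions(self) -> list[int]:
        """Per sequence, the global position of its terminating separator."""
        return [self.seq_end(s) for s in range(self.S)]

    def to_fasta(self, handle: io.TextIOBase | None = None) -> str:
        out = io.StringIO()
        for s in range(self.S):
            out.write(f">{self.seq_names[s]}\n{self.sequence(s)}\n")
        data = out.getvalue()
        if handle is not None:
            handle.write(data)
        return data
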