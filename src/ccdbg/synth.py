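"""Seeded toy pan-genome and read generator.

Strain 0 is a uniform random genome; each further strain is derived from it
by seeded substitutions and short indels.  Mutations avoid the first and last
``k_guard`` bases of each strain so that planted truth loci never interact
with the sequence-end bookkeeping of the graph.  Reads are sampled from the
strains with a recorded origin and at most ``planted_errors`` edits applied.

Everything is a pure function of the configuration's ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alphabet import DNA
from .pantext import PanGenomeText


@dataclass(frozen=True)
class SynthConfig:
    base_length: int = 8000
    n_strains: int = 3
    substitution_rate: float = 0.005
    indel_rate: float = 0.0005
    max_indel_len: int = 3
    read_length: int = 80
    n_reads: int = 100
    planted_errors: int = 2
    seed: int = 0
    k_guard: int = 32  # mutation-free margin at both ends of each strain

    def __post_init__(self):
        for r in (self.substitution_rate, self.indel_rate):
            if not (0.0 <= r <= 1.0):
                raise ValueError("rates must lie in [0, 1]")
        if self.base_length <= 2 * self.k_guard:
            raise ValueError("base_length must exceed twice the guard margin")


@dataclass(frozen=True)
class Mutation:
    strain: int
    kind: str        # "sub" | "ins" | "del"
    pos: int         # position in the base genome
    ref: str
    alt: str


@dataclass(frozen=True)
class PlantedRead:
    name: str
    seq: str
    origin_seq: int
    origin_pos: int
    planted_ed: int


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(DNA[i] for i in rng.integers(0, 4, size=length))


def generate_pan_genome(cfg: SynthConfig) -> tuple[PanGenomeText, list[Mutation]]:
    """Pan-genome text plus the exact list of applied mutations."""
    rng = np.random.default_rng(cfg.seed)
    base = _random_dna(rng, cfg.base_length)
    strains = [base]
    truth: list[Mutation] = []
    lo, hi = cfg.k_guard, cfg.base_length - cfg.k_guard
    for s in range(1, cfg.n_strains):
        chars = list(base)
        edits: list[tuple[int, str, str, str]] = []  # (pos, kind, ref, alt)
        for pos in range(lo, hi):
            if rng.random() < cfg.substitution_rate:
                ref = chars[pos]
                alt = DNA[(DNA.index(ref) + 1 + rng.integers(3)) % 4]
                edits.append((pos, "sub", ref, alt))
            elif rng.random() < cfg.indel_rate:
                ln = int(rng.integers(1, cfg.max_indel_len + 1))
                if rng.random() < 0.5:
                    edits.append((pos, "ins", "", _random_dna(rng, ln)))
                elif pos + ln < hi:
                    edits.append((pos, "del", base[pos : pos + ln], ""))
        # apply right-to-left so base coordinates stay valid
        out = chars
        for pos, kind, ref, alt in sorted(edits, reverse=True):
            if kind == "sub":
                out[pos] = alt
            elif kind == "ins":
                out[pos:pos] = list(alt)
            else:
                del out[pos : pos + len(ref)]
            truth.append(Mutation(s, kind, pos, ref, alt))
        strains.append("".join(out))
    names = [f"strain{i}" for i in range(cfg.n_strains)]
    return PanGenomeText.from_sequences(strains, names), truth


def _apply_read_errors(
    rng: np.random.Generator, seq: str, n_errors: int
) -> tuple[str, int]:
    chars = list(seq)
    applied = 0
    for _ in range(n_errors):
        if not chars:
            break
        kind = ("sub", "ins", "del")[rng.integers(3)]
        pos = int(rng.integers(len(chars)))
        if kind == "sub":
            chars[pos] = DNA[(DNA.index(chars[pos]) + 1 + rng.integers(3)) % 4]
        elif kind == "ins":
            chars.insert(pos, DNA[rng.integers(4)])
        else:
            del chars[pos]
        applied += 1
    return "".join(chars), applied


def sample_reads(text: PanGenomeText, cfg: SynthConfig) -> list[PlantedRead]:
    """Reads with recorded true locus and an upper bound on planted distance."""
    rng = np.random.default_rng(cfg.seed + 1)
    min_len = min(text.seq_length(s) for s in range(text.S))
    if cfg.read_length > min_len:
        raise ValueError("read_length exceeds the shortest sequence")
    reads = []
    for i in range(cfg.n_reads):
        s = int(rng.integers(text.S))
        pos = int(rng.integers(text.seq_length(s) - cfg.read_length + 1))
        raw = text.sequence(s)[pos : pos + cfg.read_length]
        n_err = int(rng.integers(cfg.planted_errors + 1))
        seq, applied = _apply_read_errors(rng, raw, n_err)
        reads.append(
            PlantedRead(
                name=f"read{i}", seq=seq, origin_seq=s, origin_pos=pos,
                planted_ed=applied,
            )
        )
    return reads


def reads_to_fastq(reads: list[PlantedRead]) -> str:
    return "".join(f"@{r.name}\n{r.seq}\n+\n{'I' * len(r.seq)}\n" for r in reads)


def truth_tsv(reads: list[PlantedRead]) -> str:
    lines = ["name\torigin_seq\torigin_pos\tplanted_ed"]
    lines += [
        f"{r.name}\t{r.origin_seq}\t{r.origin_pos}\t{r.planted_ed}" for r in reads
    ]
    return "\n".join(lines) + "\n"
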