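"""In-silico restriction digestion of a genome into a fragment library.

Fragment-level Hi-C resolves contacts between restriction fragments, so the
first step of spatial eQTL mapping is a digital digest of the reference
genome with the same enzyme used to prepare the Hi-C libraries (MboI or
HindIII for the libraries emulated here).  The digest produces, per
chromosome, an ordered, gap-free tiling of fragments; variants and genes are
then located on fragments by binary search and interval overlap.

Coordinates are 0-based half-open throughout this module.  1-based positions
(VCF convention) are converted at the parsing boundary by the caller.
"""

from __future__ import annotations

import re
from bisect import bisect_right
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from pyfaidx import Fasta

__all__ = [
    "IUPAC",
    "RestrictionEnzyme",
    "Fragment",
    "FragmentLibrary",
    "KNOWN_ENZYMES",
    "get_enzyme",
    "digest_sequence",
    "build_fragment_library",
]

# IUPAC nucleotide codes expanded over {A,C,G,T}; N in the genome is an
# unknown base and matches only the recognition code N.
IUPAC: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGTN",
}


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A restriction enzyme as a recognition word plus a top-strand cut offset.

    ``cut_offset`` counts bases from the 5' start of the recognition word to
    the cut position: MboI cuts ^GATC (offset 0), HindIII cuts A^AGCTT
    (offset 1).
    """

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        word = self.recognition.upper()
        if len(word) < 4:
            raise ValueError(f"recognition word {word!r} shorter than 4 bases")
        bad = [c for c in word if c not in IUPAC]
        if bad:
            raise ValueError(f"recognition word {word!r} contains non-IUPAC codes {bad}")
        if not 0 <= self.cut_offset <= len(word):
            raise ValueError(
                f"cut_offset {self.cut_offset} outside [0, {len(word)}] for {word!r}"
            )
        object.__setattr__(self, "recognition", word)

    @property
    def site_pattern(self) -> re.Pattern:
        # lookahead so overlapping occurrences all produce cuts
        body = "".join(f"[{IUPAC[c]}]" for c in self.recognition)
        return re.compile(f"(?={body})")


KNOWN_ENZYMES: dict[str, RestrictionEnzyme] = {
    "MboI": RestrictionEnzyme("MboI", "GATC", 0),
    "HindIII": RestrictionEnzyme("HindIII", "AAGCTT", 1),
}


def get_enzyme(name: str, recognition: str | None = None, cut_offset: int | None = None) -> RestrictionEnzyme:
    """Look up a bundled enzyme by name, or build a custom one."""
    if recognition is not None:
        if cut_offset is None:
            raise ValueError("custom enzyme requires both recognition and cut_offset")
        return RestrictionEnzyme(name, recognition, cut_offset)
    try:
        return KNOWN_ENZYMES[name]
    except KeyError:
        raise KeyError(
            f"unknown enzyme {name!r}; known: {sorted(KNOWN_ENZYMES)}; "
            "pass recognition/cut_offset for a custom enzyme"
        ) from None


@dataclass(frozen=True)
class Fragment:
    """A restriction fragment: half-open interval, ordinal id within chromosome."""

    chromosome: str
    start: int
    end: int
    fragment_id: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty fragment [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


_VALID_SEQ = re.compile(r"[^ACGTNacgtn]")


def digest_sequence(sequence: str, enzyme: RestrictionEnzyme, chromosome: str = "chr") -> list[Fragment]:
    """Digest one chromosome sequence into its ordered fragment list.

    Cut positions are ``match_start + cut_offset`` over all (possibly
    overlapping) matches of the recognition word, deduplicated; fragments are
    the intervals between consecutive cuts plus the two terminal intervals.
    Matching is case-insensitive; N matches only the recognition code N.
    """
    if not sequence:
        raise ValueError("cannot digest an empty sequence")
    bad = _VALID_SEQ.search(sequence)
    if bad is not None:
        raise ValueError(
            f"invalid character {sequence[bad.start()]!r} at position {bad.start()} "
            f"in sequence {chromosome!r}"
        )
    seq = sequence.upper()
    cuts = sorted({m.start() + enzyme.cut_offset for m in enzyme.site_pattern.finditer(seq)})
    bounds = [0] + [c for c in cuts if 0 < c < len(seq)] + [len(seq)]
    frags = []
    fid = 0
    for s, e in zip(bounds[:-1], bounds[1:]):
        if e > s:  # zero-length intervals dropped
            frags.append(Fragment(chromosome, s, e, fid))
            fid += 1
    return frags


class FragmentLibrary:
    """Per-chromosome fragment tilings with O(log n) position -> fragment lookup."""

    def __init__(self, fragments: Mapping[str, Iterable[Fragment]]):
        self._frags: dict[str, list[Fragment]] = {}
        self._starts: dict[str, list[int]] = {}
        for chrom, frs in fragments.items():
            frs = sorted(frs, key=lambda f: f.start)
            self._check_tiling(chrom, frs)
            self._frags[chrom] = frs
            self._starts[chrom] = [f.start for f in frs]

    @staticmethod
    def _check_tiling(chrom: str, frs: list[Fragment]) -> None:
        if not frs:
            raise ValueError(f"no fragments for chromosome {chrom!r}")
        if frs[0].start != 0:
            raise ValueError(f"{chrom}: tiling does not start at 0")
        for a, b in zip(frs[:-1], frs[1:]):
            if a.end != b.start:
                raise ValueError(f"{chrom}: gap or overlap at [{a.end}, {b.start})")
        for i, f in enumerate(frs):
            if f.fragment_id != i:
                raise ValueError(f"{chrom}: fragment_ids not consecutive from 0")

    @property
    def chromosomes(self) -> list[str]:
        return list(self._frags)

    def fragments(self, chromosome: str) -> list[Fragment]:
        try:
            return self._frags[chromosome]
        except KeyError:
            raise KeyError(f"unknown chromosome {chromosome!r}") from None

    def chromosome_length(self, chromosome: str) -> int:
        return self.fragments(chromosome)[-1].end

    def n_fragments(self, chromosome: str | None = None) -> int:
        if chromosome is not None:
            return len(self.fragments(chromosome))
        return sum(len(v) for v in self._frags.values())

    def get(self, chromosome: str, fragment_id: int) -> Fragment:
        frs = self.fragments(chromosome)
        if not 0 <= fragment_id < len(frs):
            raise IndexError(f"no fragment {fragment_id} on {chromosome}")
        return frs[fragment_id]

    def locate(self, chromosome: str, position: int) -> Fragment:
        """Return the fragment containing a 1-based ``position``."""
        frs = self.fragments(chromosome)
        length = frs[-1].end
        if not 1 <= position <= length:
            raise ValueError(
                f"position {position} outside [1, {length}] on {chromosome}"
            )
        idx = bisect_right(self._starts[chromosome], position - 1) - 1
        return frs[idx]

    def overlapping(self, chromosome: str, start: int, end: int) -> list[Fragment]:
        """Fragments overlapping the 0-based half-open interval [start, end) by >= 1 base."""
        if end <= start:
            return []
        frs = self.fragments(chromosome)
        start = max(start, 0)
        end = min(end, frs[-1].end)
        if end <= start:
            return []
        first = self.locate(chromosome, start + 1).fragment_id
        last = self.locate(chromosome, end).fragment_id  # end-1 zero-based
        return frs[first : last + 1]

    # -- serialization (BED-style TSV: chromosome, start, end, fragment_id) --

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (f.chromosome, f.start, f.end, f.fragment_id)
            for chrom in self._frags
            for f in self._frags[chrom]
        ]
        return pd.DataFrame(rows, columns=["chromosome", "start", "end", "fragment_id"])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FragmentLibrary":
        frags: dict[str, list[Fragment]] = {}
        for row in df.itertuples(index=False):
            frags.setdefault(str(row.chromosome), []).append(
                Fragment(str(row.chromosome), int(row.start), int(row.end), int(row.fragment_id))
            )
        return cls(frags)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FragmentLibrary":
        return cls.from_frame(pd.read_csv(path, sep="\t"))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FragmentLibrary):
            return NotImplemented
        return self._frags == other._frags


def build_fragment_library(
    genome: str | Path | Mapping[str, str], enzyme: RestrictionEnzyme
) -> FragmentLibrary:
    """Digest every chromosome of a genome (FASTA path or name->sequence mapping)."""
    if isinstance(genome, (str, Path)):
        fa = Fasta(str(genome))
        names = list(fa.keys())
        sequences = {name: str(fa[name][:]) for name in names}
    else:
        sequences = dict(genome)
    if len(set(sequences)) != len(sequences):
        raise ValueError("duplicate chromosome names in genome")
    return FragmentLibrary(
        {chrom: digest_sequence(seq, enzyme, chrom) for chrom, seq in sequences.items()}
    )
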