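"""Reference model of the cT-DNA locus.

Houses the reference sequence, its 1-based inclusive coordinate system, and
the feature geometry (cT-DNA span, terminal inverted repeats, gene intervals)
that every downstream stage refers to.

Coordinates
-----------
All feature coordinates are 1-based inclusive on the full analysis window
(left plant flank + cT-DNA + right plant flank): position 1 is the first
flank base, so a 200-nt flank puts the cT-DNA at 201..201+L-1 and the left
repeat's first printed coordinate is 201. Conversion to 0-based string
indices happens in exactly one place, :meth:`ReferenceMap.seq_index`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._align import revcomp

_VALID_BASES = set("ACGTN")


@dataclass(frozen=True)
class Interval:
    """1-based inclusive interval; length = end - start + 1."""

    start: int
    end: int

    def __post_init__(self):
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"malformed interval {self.start}..{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "Interval") -> bool:
        return self.start <= other.end and other.start <= self.end


@dataclass
class ReferenceMap:
    """The reference locus plus named feature intervals.

    Attributes
    ----------
    sequence : str
        Full analysis window: left flank + cT-DNA + right flank.
    ctdna_span : Interval
        The cT-DNA on the window (flank_len+1 .. len(sequence)-flank_len).
    left_ir, right_ir : Interval
        The terminal inverted repeats. The right repeat is stored as its
        forward-strand interval; reverse complementation happens only inside
        repeat-comparison operations.
    genes : dict[str, Interval]
        Named gene intervals (acs, susL, rolB ... all forward frame, anchored
        at the interval start).
    flank_len : int
        Plant-flank length on each side of the cT-DNA.
    """

    sequence: str
    ctdna_span: Interval
    left_ir: Interval
    right_ir: Interval
    genes: dict[str, Interval] = field(default_factory=dict)
    flank_len: int = 0

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise ValueError(f"non-ACGTN characters in reference: {sorted(bad)}")
        if self.ctdna_span.start != self.flank_len + 1:
            raise ValueError("cT-DNA span must start right after the left flank")
        if self.ctdna_span.end != len(self.sequence) - self.flank_len:
            raise ValueError("cT-DNA span must end right before the right flank")
        for name, iv in self._named().items():
            if iv.end > len(self.sequence):
                raise ValueError(f"feature {name} ({iv.start}..{iv.end}) outside the sequence")
            if name != "ctdna" and not (
                self.ctdna_span.start <= iv.start and iv.end <= self.ctdna_span.end
            ):
                raise ValueError(f"feature {name} ({iv.start}..{iv.end}) outside the cT-DNA span")
        if self.left_ir.start >= self.right_ir.start or self.left_ir.overlaps(self.right_ir):
            raise ValueError("left IR must precede and not overlap the right IR")

    # -- coordinate handling -------------------------------------------------

    def seq_index(self, pos: int) -> int:
        """Window 1-based position -> 0-based index into ``sequence``.

        This is the single documented conversion boundary.
        """
        if not 1 <= pos <= len(self.sequence):
            raise ValueError(f"position {pos} outside the analysis window")
        return pos - 1

    def subsequence(self, iv: Interval) -> str:
        return self.sequence[self.seq_index(iv.start) : self.seq_index(iv.end) + 1]

    def _named(self) -> dict[str, Interval]:
        d = {"ctdna": self.ctdna_span, "left_ir": self.left_ir, "right_ir": self.right_ir}
        d.update(self.genes)
        return d

    def feature(self, name: str) -> Interval:
        try:
            return self._named()[name]
        except KeyError:
            raise KeyError(f"unknown feature {name!r}") from None

    def feature_seq(self, name: str) -> str:
        return self.subsequence(self.feature(name))

    @property
    def ctdna_seq(self) -> str:
        return self.feature_seq("ctdna")

    @property
    def left_ir_seq(self) -> str:
        return self.feature_seq("left_ir")

    @property
    def right_ir_seq_rc(self) -> str:
        """Right repeat reverse-complemented into left-repeat orientation."""
        return revcomp(self.feature_seq("right_ir"))

    @property
    def window_len(self) -> int:
        return len(self.sequence)


def feature_length(refmap: ReferenceMap, feature: str) -> int:
    """Length in nt of a named feature (end - start + 1)."""
    return refmap.feature(feature).length


def load_reference(fasta_path, features_path) -> ReferenceMap:
    """Load a ReferenceMap from a single-record FASTA and a feature TSV.

    The feature table is tab-separated ``name<TAB>start<TAB>end`` with 1-based
    inclusive window coordinates; '#' lines are comments. It must supply
    ``ctdna``, ``left_ir`` and ``right_ir``; every other row becomes a gene.
    The flank length is inferred from the cT-DNA span's offset in the window.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"reference FASTA must contain exactly one record, got {len(records)}")
    sequence = str(records[0].seq).upper()

    intervals: dict[str, Interval] = {}
    with open(features_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"malformed feature row: {line!r}")
            name, start, end = parts[0], int(parts[1]), int(parts[2])
            intervals[name] = Interval(start, end)
    for required in ("ctdna", "left_ir", "right_ir"):
        if required not in intervals:
            raise ValueError(f"feature table missing required interval {required!r}")
    span = intervals.pop("ctdna")
    left = intervals.pop("left_ir")
    right = intervals.pop("right_ir")
    return ReferenceMap(
        sequence=sequence,
        ctdna_span=span,
        left_ir=left,
        right_ir=right,
        genes=intervals,
        flank_len=span.start - 1,
    )


def write_reference(refmap: ReferenceMap, fasta_path, features_path, name: str = "reference") -> None:
    """Write the FASTA + feature TSV representation (round-trips losslessly)."""
    SeqIO.write([SeqRecord(Seq(refmap.sequence), id=name, description="")], str(fasta_path), "fasta")
    with open(features_path, "w") as fh:
        fh.write("# name\tstart\tend (1-based inclusive, cT-DNA-local)\n")
        for fname, iv in refmap._named().items():
            fh.write(f"{fname}\t{iv.start}\t{iv.end}\n")
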