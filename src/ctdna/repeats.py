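"""Terminal inverted repeat comparison, structural classification, and the
gene-disruption scan.

The percent identity of the two repeat copies is the raw material of the
molecular-clock dating: identity = matches / alignment columns, where the
end-free terminal overhang columns are excluded from the denominator and
internal gap columns count as mismatches (the two repeat annotations differ
in length, so a strictly global denominator could never reach 100%).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib

from ._align import (
    global_cigar,
    identity_excluding_terminal_gaps,
    parse_cigar,
    ref_to_query_map,
    revcomp,
)
from .reference import ReferenceMap


@dataclass
class RepeatPair:
    allele_id: str
    left: str
    right: str  # reverse-complemented into left orientation
    aligned_columns: int
    identity: float  # percent
    resolved: bool = True
    reason: str = ""

    @property
    def divergence(self) -> float:
        return 1.0 - self.identity / 100.0

    @classmethod
    def from_counts(cls, mismatches: int, columns: int, allele_id: str = "synthetic") -> "RepeatPair":
        """A repeat pair summarized by its mismatch count (worked examples)."""
        ident = 100.0 * (columns - mismatches) / columns
        return cls(allele_id, "", "", aligned_columns=columns, identity=ident)


@dataclass
class StructureCall:
    allele_id: str
    structural_class: str  # standard | inverted_center | unresolved
    central_interval: tuple[int, int] | None = None  # 0-based half-open on allele
    breakpoint_deletions: list[int] = field(default_factory=list)  # [left nt, right nt]
    reason: str = ""


@dataclass
class GeneDisruption:
    allele_id: str
    gene: str
    kind: str  # premature_stop | frameshift | truncation
    position: int  # window 1-based; stop positions index the codon's last base
    context: str


def orient_to_reference(allele_seq: str, refmap: ReferenceMap) -> str:
    """Return the allele in reference orientation.

    Orientation is anchored on the plant flanks: a locus bounded by terminal
    inverted repeats is nearly palindromic, so a centrally inverted allele
    scores deceptively well in reverse complement over the whole window. The
    flanks are the only unambiguous strand witnesses; the whole sequence is
    the fallback when flanks are missing or indecisive.
    """
    probe = max(refmap.flank_len, 50)
    if len(allele_seq) > 4 * probe:
        ref_probe = refmap.sequence[:probe] + refmap.sequence[-probe:]
        rc = revcomp(allele_seq)
        d_f = edlib.align(allele_seq[:probe] + allele_seq[-probe:], ref_probe, mode="NW")[
            "editDistance"
        ]
        d_r = edlib.align(rc[:probe] + rc[-probe:], ref_probe, mode="NW")["editDistance"]
        if abs(d_f - d_r) >= 0.1 * probe:
            return rc if d_r < d_f else allele_seq
    fwd = edlib.align(allele_seq, refmap.sequence, mode="NW")["editDistance"]
    rev = edlib.align(revcomp(allele_seq), refmap.sequence, mode="NW")["editDistance"]
    return revcomp(allele_seq) if rev < fwd else allele_seq


def _lift_interval(allele: str, refmap: ReferenceMap, start: int, end: int) -> tuple[int, int]:
    """Map a cT-DNA 1-based interval onto 0-based allele indices [lo, hi)."""
    cigar = global_cigar(allele, refmap.sequence)
    mapping = ref_to_query_map(cigar)
    lo = mapping[refmap.seq_index(start)]
    hi_ref = refmap.seq_index(end)
    hi = mapping.get(hi_ref + 1, len(allele) if hi_ref + 1 >= len(refmap.sequence) else None)
    if hi is None:
        hi = len(allele)
    return lo, hi


def extract_repeats(allele_seq: str, refmap: ReferenceMap, allele_id: str = "allele") -> RepeatPair:
    """Lift both repeat intervals onto the allele and compare the copies.

    The right copy is reverse-complemented into left orientation; the shorter
    copy is aligned end-free inside the longer one, and identity is computed
    over the covered columns.
    """
    allele = orient_to_reference(allele_seq.upper(), refmap)
    l_lo, l_hi = _lift_interval(allele, refmap, refmap.left_ir.start, refmap.left_ir.end)
    r_lo, r_hi = _lift_interval(allele, refmap, refmap.right_ir.start, refmap.right_ir.end)
    left = allele[l_lo:l_hi]
    right = revcomp(allele[r_lo:r_hi])
    if len(left) < 0.5 * refmap.left_ir.length or len(right) < 0.5 * refmap.right_ir.length:
        return RepeatPair(allele_id, left, right, 0, 0.0, resolved=False, reason="repeat_deleted")
    query, target = (left, right) if len(left) <= len(right) else (right, left)
    res = edlib.align(query, target, mode="HW", task="path")
    identity, columns = identity_excluding_terminal_gaps(parse_cigar(res["cigar"]))
    return RepeatPair(allele_id, left, right, columns, identity)


def classify_structure(
    allele_seq: str, refmap: ReferenceMap, allele_id: str = "allele", margin: int = 10
) -> StructureCall:
    """Orient the inter-repeat central segment against the reference.

    The segment between the repeats is aligned in both orientations; the
    allele is called ``inverted_center`` when the reverse-complement
    alignment wins by at least ``margin`` edits. Junction deletions are
    estimated from the aligned block's offsets relative to the repeat
    boundaries.
    """
    allele = orient_to_reference(allele_seq.upper(), refmap)
    c_lo = refmap.seq_index(refmap.left_ir.end) + 1
    c_hi = refmap.seq_index(refmap.right_ir.start)
    central_ref = refmap.sequence[c_lo:c_hi]
    if len(central_ref) < 200:
        return StructureCall(allele_id, "unresolved", reason="central_segment_too_short")
    fwd = edlib.align(central_ref, allele, mode="HW", task="locations")
    rev = edlib.align(revcomp(central_ref), allele, mode="HW", task="locations")
    if rev["editDistance"] + margin < fwd["editDistance"]:
        s, e = rev["locations"][0]
        left_arm = c_lo  # expected allele index where the central segment starts
        right_arm = len(refmap.sequence) - c_hi  # expected allele suffix length
        del_left = max(0, left_arm - s)
        del_right = max(0, right_arm - (len(allele) - (e + 1)))
        return StructureCall(
            allele_id, "inverted_center", central_interval=(s, e + 1),
            breakpoint_deletions=[del_left, del_right],
        )
    s, e = fwd["locations"][0]
    return StructureCall(allele_id, "standard", central_interval=(s, e + 1))


_STOPS = {"TAA", "TAG", "TGA"}


def scan_gene_disruptions(
    allele_seq: str, refmap: ReferenceMap, allele_id: str = "allele"
) -> list[GeneDisruption]:
    """Translate each annotated gene on the allele and report disruptions.

    Premature stops are reported at the cT-DNA coordinate of the stop
    codon's last base with a 12-nt context ending at that base; frameshifts
    are reported where an indel of length not divisible by 3 falls inside
    the gene; truncations where part of the gene interval is missing.
    Downstream of a frameshift, stops are scanned in the shifted frame (an
    ORF scan of what the allele actually encodes).
    """
    allele = orient_to_reference(allele_seq.upper(), refmap)
    cigar = global_cigar(allele, refmap.sequence)
    mapping = ref_to_query_map(cigar)
    out: list[GeneDisruption] = []

    # per-gene indel bookkeeping from the alignment
    for gene, iv in sorted(refmap.genes.items(), key=lambda kv: kv[1].start):
        g_lo = refmap.seq_index(iv.start)
        g_hi = refmap.seq_index(iv.end)
        qi = ti = 0
        shift = 0
        truncated = 0
        for n, op in cigar:
            if op in "=XM":
                qi += n
                ti += n
            elif op == "D":
                overlap = max(0, min(ti + n, g_hi + 1) - max(ti, g_lo))
                if overlap:
                    shift -= overlap
                    if overlap >= 30:
                        truncated += overlap
                    elif overlap % 3:
                        out.append(
                            GeneDisruption(
                                allele_id, gene, "frameshift",
                                position=ti,
                                context=allele[max(0, qi - 10) : qi],
                            )
                        )
                ti += n
            elif op == "I":
                if g_lo <= ti <= g_hi:
                    shift += n
                    if n % 3:
                        out.append(
                            GeneDisruption(
                                allele_id, gene, "frameshift",
                                position=ti,
                                context=allele[max(0, qi + n - 10) : qi + n],
                            )
                        )
                qi += n
        if truncated:
            out.append(
                GeneDisruption(
                    allele_id, gene, "truncation", position=iv.start,
                    context=f"{truncated}nt_missing",
                )
            )

        # ORF scan in the frame anchored at the (lifted) gene start
        a_lo = mapping[g_lo]
        a_hi = mapping.get(g_hi + 1, len(allele))
        coding = allele[a_lo:a_hi]
        n_codons = len(coding) // 3
        for c in range(n_codons - 1):  # a stop in the final codon is not premature
            codon = coding[3 * c : 3 * c + 3]
            if codon in _STOPS:
                q_last = a_lo + 3 * c + 2
                # map the stop's last base back to a reference coordinate
                ref_positions = [t for t, q in mapping.items() if q == q_last]
                ref_pos = (min(ref_positions) if ref_positions else g_lo + 3 * c + 2)
                out.append(
                    GeneDisruption(
                        allele_id, gene, "premature_stop",
                        position=ref_pos + 1,
                        context=allele[max(0, q_last - 11) : q_last + 1],
                    )
                )
                break  # report the first premature stop per gene
    return out
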