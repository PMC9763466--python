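"""Shared low-level sequence and alignment helpers.

Pairwise alignment uses edlib (unit-cost edit distance with extended-CIGAR
paths) for speed, refined by affine-gap local realignment of indel-bearing
regions for correct gap placement. Reference feature coordinates elsewhere
in the package are 1-based inclusive on the analysis window; the 0-based
string indices live inside this module and at documented call sites.
"""

from __future__ import annotations

import re

import edlib
from Bio import Align

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")

# Affine-gap scores for local realignment (match, mismatch, open, extend).
# Unit-cost edit-distance alignments leave long indels scattered across
# cost-tied mismatch paths; realigning with a gap-open penalty restores
# contiguous gap runs.
_AFFINE = (1, -1, -4, -1)


def _affine_aligner(free_left: bool = False, free_right: bool = False) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = _AFFINE[0]
    aligner.mismatch_score = _AFFINE[1]
    aligner.open_gap_score = _AFFINE[2]
    aligner.extend_gap_score = _AFFINE[3]
    if free_left:  # unconsumed target allowed before the query starts
        aligner.open_left_insertion_score = 0.0
        aligner.extend_left_insertion_score = 0.0
    if free_right:  # unconsumed target allowed after the query ends
        aligner.open_right_insertion_score = 0.0
        aligner.extend_right_insertion_score = 0.0
    return aligner


_ALIGNERS: dict[tuple[bool, bool], Align.PairwiseAligner] = {}


def _affine_cigar(
    query: str, target: str, free_left: bool = False, free_right: bool = False
) -> list[tuple[int, str]]:
    """Affine-gap global alignment of two (short) segments as cigar ops."""
    key = (free_left, free_right)
    if key not in _ALIGNERS:
        _ALIGNERS[key] = _affine_aligner(*key)
    if not query and not target:
        return []
    if not query:
        return [(len(target), "D")]
    if not target:
        return [(len(query), "I")]
    aln = _ALIGNERS[key].align(query, target)[0]
    q_blocks, t_blocks = aln.aligned
    ops: list[tuple[int, str]] = []
    qp = tp = 0
    for (qs, qe), (ts, te) in zip(q_blocks, t_blocks):
        qs, qe, ts, te = int(qs), int(qe), int(ts), int(te)
        if qs > qp:
            ops.append((qs - qp, "I"))
        if ts > tp:
            ops.append((ts - tp, "D"))
        for q, t in zip(query[qs:qe], target[ts:te]):
            op = "=" if q == t else "X"
            if ops and ops[-1][1] == op:
                ops[-1] = (ops[-1][0] + 1, op)
            else:
                ops.append((1, op))
        qp, tp = qe, te
    if len(query) > qp:
        ops.append((len(query) - qp, "I"))
    if len(target) > tp:
        ops.append((len(target) - tp, "D"))
    return ops


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    """Parse an extended CIGAR string into (length, op) pairs."""
    return [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]


def global_cigar(query: str, target: str) -> list[tuple[int, str]]:
    """Global alignment path of query vs target with affine-refined indels.

    Ops are relative to the query: 'I' consumes query only (insertion in the
    query), 'D' consumes target only (deletion from the query). The path is
    computed with edlib (fast, unit costs) and every indel-bearing region is
    locally realigned with affine gap penalties so gap runs stay contiguous.
    """
    res = edlib.align(query, target, mode="NW", task="path")
    return refine_cigar(query, target, parse_cigar(res["cigar"]))


def refine_cigar(
    query: str,
    target: str,
    cigar: list[tuple[int, str]],
    t_offset: int = 0,
    anchor: int = 20,
) -> list[tuple[int, str]]:
    """Realign indel-bearing cigar regions with affine gap penalties.

    Maximal op runs that contain an I/D and are bounded by match runs of at
    least ``anchor`` nt are re-aligned segment-by-segment; pure-match/
    mismatch alignments are returned unchanged. ``t_offset`` is the target
    position where the cigar starts (for infix alignments).
    """
    if not any(op in "ID" for _, op in cigar):
        return cigar
    # split into alternating clean anchors and dirty clusters
    out: list[tuple[int, str]] = []
    qp, tp = 0, t_offset
    cluster: list[tuple[int, str]] = []
    cluster_q, cluster_t = 0, t_offset

    def flush(upto_q: int, upto_t: int) -> None:
        nonlocal cluster
        if cluster:
            if any(op in "ID" for _, op in cluster):
                seg = _affine_cigar(query[cluster_q:upto_q], target[cluster_t:upto_t])
            else:
                seg = cluster
            for n, op in seg:
                if out and out[-1][1] == op:
                    out[-1] = (out[-1][0] + n, op)
                else:
                    out.append((n, op))
            cluster = []

    for n, op in cigar:
        if op == "=" and n >= anchor:
            flush(qp, tp)
            if out and out[-1][1] == "=":
                out[-1] = (out[-1][0] + n, "=")
            else:
                out.append((n, "="))
            qp += n
            tp += n
            cluster_q, cluster_t = qp, tp
        else:
            if not cluster:
                cluster_q, cluster_t = qp, tp
            cluster.append((n, op))
            if op in "=XM":
                qp += n
                tp += n
            elif op == "I":
                qp += n
            elif op == "D":
                tp += n
    flush(qp, tp)
    return out


def refine_infix_cigar(
    query: str,
    target: str,
    cigar: list[tuple[int, str]],
    t_offset: int,
    anchor: int = 20,
    reach: int = 60,
) -> tuple[list[tuple[int, str]], int]:
    """Affine refinement for infix (read-vs-locus) alignments.

    Like :func:`refine_cigar`, but terminal dirty clusters are realigned
    against a target window extended by ``reach`` nt beyond the original
    alignment span, with free target end-gaps on the open side. A read whose
    head or tail crosses a long deletion otherwise gets those bases aligned
    as edit-dense junk, because the edit-distance alignment will not extend
    the target past its chosen endpoint. Returns (ops, new target start).
    """
    if not any(op in "ID" for _, op in cigar):
        return cigar, t_offset

    # split the path into anchors and dirty clusters with coordinates
    segs: list[tuple[str, list, int, int, int, int]] = []
    qp, tp = 0, t_offset
    cur: list[tuple[int, str]] = []
    cur_q, cur_t = 0, t_offset
    for n, op in cigar:
        if op == "=" and n >= anchor:
            if cur:
                segs.append(("dirty", cur, cur_q, qp, cur_t, tp))
                cur = []
            segs.append(("anchor", [(n, "=")], qp, qp + n, tp, tp + n))
            qp += n
            tp += n
            cur_q, cur_t = qp, tp
        else:
            if not cur:
                cur_q, cur_t = qp, tp
            cur.append((n, op))
            if op in "=XM":
                qp += n
                tp += n
            elif op == "I":
                qp += n
            elif op == "D":
                tp += n
    if cur:
        segs.append(("dirty", cur, cur_q, qp, cur_t, tp))

    out: list[tuple[int, str]] = []
    t_start = t_offset

    def emit(ops):
        for n, op in ops:
            if out and out[-1][1] == op:
                out[-1] = (out[-1][0] + n, op)
            else:
                out.append((n, op))

    for idx, (kind, ops, q0, q1, s0, s1) in enumerate(segs):
        if kind == "anchor" or not any(op in "ID" for _, op in ops):
            emit(ops)
            continue
        first = idx == 0
        last = idx == len(segs) - 1
        t_lo = max(0, s1 - (q1 - q0) - reach) if first else s0
        t_hi = min(len(target), s0 + (q1 - q0) + reach) if last else s1
        seg_ops = _affine_cigar(
            query[q0:q1], target[t_lo:t_hi], free_left=first, free_right=last
        )
        if first:
            lead = 0
            if seg_ops and seg_ops[0][1] == "D":
                lead = seg_ops[0][0]
                seg_ops = seg_ops[1:]
            t_start = t_lo + lead
        if last and seg_ops and seg_ops[-1][1] == "D":
            seg_ops = seg_ops[:-1]
        emit(seg_ops)
    return out, t_start


def identity_excluding_terminal_gaps(cigar: list[tuple[int, str]]) -> tuple[float, int]:
    """Percent identity over alignment columns, excluding terminal gap runs.

    Internal gap columns and mismatch columns count against identity (the
    denominator is the number of non-terminal alignment columns). Returns
    (identity in percent, number of columns counted).
    """
    ops = list(cigar)
    # strip terminal gap runs (overhangs of either sequence)
    while ops and ops[0][1] in "ID":
        ops.pop(0)
    while ops and ops[-1][1] in "ID":
        ops.pop()
    matches = sum(n for n, op in ops if op == "=")
    columns = sum(n for n, op in ops)
    if columns == 0:
        return 0.0, 0
    return 100.0 * matches / columns, columns


def ref_to_query_map(cigar: list[tuple[int, str]]) -> dict[int, int]:
    """Map 0-based target positions to 0-based query positions.

    For target positions deleted from the query, maps to the next query
    position (so interval extraction stays well defined).
    """
    mapping: dict[int, int] = {}
    qi = ti = 0
    for n, op in cigar:
        if op in "=XM":
            for _ in range(n):
                mapping[ti] = qi
                qi += 1
                ti += 1
        elif op == "I":
            qi += n
        elif op == "D":
            for _ in range(n):
                mapping[ti] = qi
                ti += 1
    return mapping


def normalize_deletion(ref: str, pos: int, length: int) -> tuple[int, str]:
    """Left-align a deletion of ref[pos+1 .. pos+length] (1-based coords).

    ``pos`` is the 1-based coordinate of the last reference base before the
    deleted run; 0 means the run starts at the first base. Shifts the run
    5'-ward while the base entering the run from the left equals the base
    leaving it on the right. Returns (pos, deleted sequence).
    """
    while pos >= 1 and pos + length <= len(ref) and ref[pos - 1] == ref[pos + length - 1]:
        pos -= 1
    return pos, ref[pos : pos + length]


def normalize_insertion(ref: str, pos: int, seq: str) -> tuple[int, str]:
    """Left-align an insertion of ``seq`` after 1-based reference ``pos``.

    An insertion after ``pos`` is equivalent to inserting the rotated string
    after ``pos - 1`` whenever the insert's last base equals ref[pos].
    """
    while pos >= 1 and seq and seq[-1] == ref[pos - 1]:
        seq = ref[pos - 1] + seq[:-1]
        pos -= 1
    return pos, seq


def deletion_placements(ref: str, pos: int, length: int) -> list[int]:
    """All equivalent 1-based placements of a deletion (for ambiguity flags)."""
    left, _ = normalize_deletion(ref, pos, length)
    placements = [left]
    p = left
    while p + length < len(ref) and ref[p] == ref[p + length]:
        p += 1
        placements.append(p)
    return placements


def insertion_placements(ref: str, pos: int, seq: str) -> list[int]:
    """All equivalent 1-based placements of an insertion."""
    left, s = normalize_insertion(ref, pos, seq)
    placements = [left]
    p, cur = left, s
    while p < len(ref) and cur and cur[0] == ref[p]:
        cur = cur[1:] + ref[p]
        p += 1
        placements.append(p)
    return placements


def apply_indels(seq: str, events) -> str:
    """Apply (position, type, sequence) events to a reference-length string.

    Positions are 1-based "last base before the modification" on ``seq``
    itself. Events must not overlap; they are applied right-to-left so earlier
    coordinates stay valid. ``type`` is "del" for deletions, anything else is
    treated as an insertion of ``sequence`` after ``position``.
    """
    out = seq
    for ev in sorted(events, key=lambda e: e[0], reverse=True):
        pos, kind, s = ev[0], ev[1], ev[2]
        if kind == "del":
            out = out[:pos] + out[pos + len(s) :]
        else:
            out = out[:pos] + s + out[pos:]
    return out
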