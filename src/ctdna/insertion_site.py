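"""Insertion-site reconstruction: empty-site vs filled-site comparison.

Aligns a pre-insertion ("empty") locus against a filled one by chaining
unique k-mer anchors, reports segments private to either sequence, and
annotates filled-site inserts with target-site duplications (TSDs) and
terminal inverted repeats — the signature left by mobile-element-like
insertions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib

from ._align import revcomp


@dataclass
class InsertCall:
    insert_id: str
    kind: str  # filled_only | empty_only
    start: int  # 0-based half-open interval on the carrying sequence
    end: int
    tsd: str = ""
    terminal_ir_length: int = 0
    terminal_ir_seq: str = ""
    replacement: bool = False  # paired with a segment in the other sequence
    presence: dict[str, bool] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return self.end - self.start

    def sequence(self, carrier: str) -> str:
        return carrier[self.start : self.end]


def _unique_kmers(seq: str, k: int) -> dict[str, int]:
    """Positions of k-mers occurring exactly once in ``seq``."""
    seen: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        seen[kmer] = seen.get(kmer, 0) + 1
    return {
        seq[i : i + k]: i
        for i in range(len(seq) - k + 1)
        if seen[seq[i : i + k]] == 1
    }


def _anchor_chain(empty: str, filled: str, k: int) -> list[tuple[int, int]]:
    """Colinear chain of shared unique k-mer anchors (LIS on filled pos)."""
    ue = _unique_kmers(empty, k)
    uf = _unique_kmers(filled, k)
    pairs = sorted((pe, uf[kmer]) for kmer, pe in ue.items() if kmer in uf)
    if not pairs:
        return []
    # longest strictly-increasing subsequence in the filled coordinate
    import bisect

    tails: list[int] = []
    tidx: list[int] = []
    prev = [-1] * len(pairs)
    for i, (_, pf) in enumerate(pairs):
        j = bisect.bisect_left(tails, pf)
        if j == len(tails):
            tails.append(pf)
            tidx.append(i)
        else:
            tails[j] = pf
            tidx[j] = i
        prev[i] = tidx[j - 1] if j > 0 else -1
    chain = []
    i = tidx[-1]
    while i != -1:
        chain.append(pairs[i])
        i = prev[i]
    return chain[::-1]


def _merge_blocks(chain: list[tuple[int, int]], k: int) -> list[tuple[int, int, int]]:
    """Merge co-offset consecutive anchors into blocks (e_start, f_start, length)."""
    blocks: list[list[int]] = []
    for pe, pf in chain:
        if blocks and pf - pe == blocks[-1][1] - blocks[-1][0] and pe <= blocks[-1][0] + blocks[-1][2]:
            blocks[-1][2] = pe + k - blocks[-1][0]
        else:
            blocks.append([pe, pf, k])
    return [tuple(b) for b in blocks]


def align_empty_vs_filled(
    empty: str, filled: str, k: int = 21, min_len: int = 10
) -> list[InsertCall]:
    """Report segments private to the filled or the empty sequence.

    Colinear unique-anchor chaining followed by maximal boundary extension;
    a gap present only in the filled sequence is a filled-site insert, a gap
    only in the empty one is a segment lost from the filled site. Regions
    private to both at the same junction are flagged ``replacement``.
    """
    empty, filled = empty.upper(), filled.upper()
    if empty == filled:
        return []
    blocks = _merge_blocks(_anchor_chain(empty, filled, k), k)
    if not blocks:
        raise ValueError("no colinear chain found between the sequences")

    # maximal extension of each block in both directions
    ext: list[list[int]] = []
    for pe, pf, ln in blocks:
        while pe > 0 and pf > 0 and empty[pe - 1] == filled[pf - 1]:
            pe -= 1
            pf -= 1
            ln += 1
        while pe + ln < len(empty) and pf + ln < len(filled) and empty[pe + ln] == filled[pf + ln]:
            ln += 1
        ext.append([pe, pf, ln])

    # drop blocks swallowed by their neighbor's extension
    merged: list[list[int]] = []
    for b in ext:
        if merged and b[0] - merged[-1][0] == b[1] - merged[-1][1] and b[0] <= merged[-1][0] + merged[-1][2]:
            merged[-1][2] = max(merged[-1][2], b[0] + b[2] - merged[-1][0])
        else:
            merged.append(b)

    calls: list[InsertCall] = []
    idx = 0

    def junctions():
        yield (0, 0), merged[0]
        for a, b in zip(merged, merged[1:]):
            yield (a[0] + a[2], a[1] + a[2]), b
        last = merged[-1]
        yield (last[0] + last[2], last[1] + last[2]), (len(empty), len(filled), 0)

    for (e0, f0), nxt in junctions():
        e1, f1 = nxt[0], nxt[1]
        gap_e, gap_f = e1 - e0, f1 - f0
        # overlapping blocks (negative gap in one sequence) arise when a
        # target-site duplication lets both neighbors extend over the same
        # bases; trim the following block's start, which extends this gap on
        # its 3' side by the duplicated length
        if gap_e < 0:
            f1 += -gap_e
            gap_f += -gap_e
            gap_e = 0
        if gap_f < 0:
            e1 += -gap_f
            gap_e += -gap_f
            gap_f = 0
        repl = gap_e >= min_len and gap_f >= min_len
        if gap_f >= min_len:
            calls.append(InsertCall(f"ins{idx}", "filled_only", f0, f1, replacement=repl))
            idx += 1
        if gap_e >= min_len:
            calls.append(InsertCall(f"ins{idx}", "empty_only", e0, e1, replacement=repl))
            idx += 1
    return calls


def detect_tsd(call: InsertCall, carrier: str, max_len: int = 15) -> InsertCall:
    """Longest k-mer (3..max_len) duplicated at the insert's immediate flanks.

    Equivalent insert placements (the insert can slide when its ends repeat
    the flanks) are scanned and the placement maximizing the duplicated
    motif is chosen; the reported interval excludes both motif copies, so
    one copy reads as the ancestral target and one as its duplication.
    """
    s, e = call.start, call.end

    def placements():
        a, b = s, e
        yield a, b
        while a > 0 and carrier[a - 1] == carrier[b - 1]:
            a, b = a - 1, b - 1
            yield a, b
        a, b = s, e
        while b < len(carrier) and carrier[a] == carrier[b]:
            a, b = a + 1, b + 1
            yield a, b

    best = (0, s, e)
    for a, b in placements():
        for k in range(max_len, 2, -1):
            if a - k >= 0 and b + k <= len(carrier) and carrier[a - k : a] == carrier[b : b + k]:
                if k > best[0]:
                    best = (k, a, b)
                break
            # one motif copy may still sit inside the insert at either end
            if a - k >= 0 and b - k >= a and carrier[a - k : a] == carrier[b - k : b]:
                if k > best[0]:
                    best = (k, a, b - k)
                break
            if b + k <= len(carrier) and a + k <= b and carrier[a : a + k] == carrier[b : b + k]:
                if k > best[0]:
                    best = (k, a + k, b)
                break
    k, a, b = best
    if k:
        call.tsd = carrier[a - k : a]
        call.start, call.end = a, b
    return call


def detect_terminal_ir(
    call: InsertCall, carrier: str, min_len: int = 5, max_mismatch: int = 0
) -> InsertCall:
    """Longest prefix of the insert whose reverse complement ends it.

    Scans lengths from half the insert down to ``min_len``, allowing up to
    ``max_mismatch`` mismatching positions, and records the first (longest)
    hit.
    """
    ins = call.sequence(carrier)
    for length in range(len(ins) // 2, min_len - 1, -1):
        tail_rc = revcomp(ins[-length:])
        mm = sum(1 for x, y in zip(ins[:length], tail_rc) if x != y)
        if mm <= max_mismatch:
            call.terminal_ir_length = length
            call.terminal_ir_seq = ins[:length]
            return call
    call.terminal_ir_length = 0
    call.terminal_ir_seq = ""
    return call


def presence_across(insert_seq: str, others: dict[str, str], min_identity: float = 0.9) -> dict[str, bool]:
    """Flag which other (empty-site) sequences carry this insert."""
    out = {}
    for name, seq in others.items():
        res = edlib.align(insert_seq, seq, mode="HW")
        best = min(
            res["editDistance"],
            edlib.align(revcomp(insert_seq), seq, mode="HW")["editDistance"],
        )
        out[name] = (1.0 - best / len(insert_seq)) >= min_identity
    return out
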