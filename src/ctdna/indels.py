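"""Catalog of indels (>= 3 nt) across phased alleles.

Positions follow the locus convention: the 1-based cT-DNA coordinate of the
last reference nucleotide before the modification, with every event shifted
to its 5'-most (left-aligned) equivalent placement. Insertions are further
classified as tandem duplications (the insert copies the adjacent reference
segment) or plant inserts (flanked by a short direct repeat, the
target-site duplication left by a mobile-element insertion).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from ._align import (
    deletion_placements,
    global_cigar,
    insertion_placements,
    normalize_deletion,
    normalize_insertion,
)
from .reference import ReferenceMap
from .repeats import orient_to_reference


@dataclass
class IndelEvent:
    position: int  # cT-DNA-local 1-based, last unchanged base before the event
    type: str  # del | ins | dupl | plant_insert
    sequence: str  # deleted / inserted string
    direct_repeat: str = ""
    copy_number: int = 1  # tandem duplications only
    alleles: list[str] = field(default_factory=list)
    ambiguous_boundary: bool = False
    placements: list[int] = field(default_factory=list)  # equivalent positions
    compound: bool = False  # within 3 nt of another event on the same allele
    partial: bool = False  # insert contains an unresolved (N) gap marker

    @property
    def length(self) -> int:
        return len(self.sequence)

    def key(self) -> tuple:
        return (self.position, self.type, self.sequence, self.direct_repeat)


def call_indels(allele_seq: str, refmap: ReferenceMap, min_len: int = 3) -> list[IndelEvent]:
    """Gap runs >= min_len in the allele/reference alignment, left-aligned.

    Deletion sequences are reported from the reference, insertions from the
    allele. Events whose gap runs sit closer than 3 nt on the reference are
    flagged ``compound`` (the alignment cannot uniquely decompose them).
    """
    if not allele_seq:
        raise ValueError("empty allele sequence")
    allele = orient_to_reference(allele_seq.upper(), refmap)
    cigar = global_cigar(allele, refmap.sequence)
    ref = refmap.sequence

    raw: list[tuple[int, str, str]] = []  # (last ref base before event, kind, seq)
    qi = ti = 0
    for n, op in cigar:
        if op in "=XM":
            qi += n
            ti += n
        elif op == "D":  # reference-only: deletion from the allele
            if n >= min_len:
                raw.append((ti, "del", ref[ti : ti + n]))
            ti += n
        elif op == "I":  # allele-only: insertion
            if n >= min_len:
                raw.append((ti, "ins", allele[qi : qi + n]))
            qi += n

    events: list[IndelEvent] = []
    for pos0, kind, seq in raw:
        # pos0 (a 0-based index of the first event base on the reference)
        # doubles as the 1-based "last base before" coordinate; left-align
        # against the reference window.
        if kind == "del":
            pos, nseq = normalize_deletion(ref, pos0, len(seq))
            placements = deletion_placements(ref, pos, len(nseq))
        else:
            pos, nseq = normalize_insertion(ref, pos0, seq)
            placements = insertion_placements(ref, pos, nseq)
        events.append(
            IndelEvent(
                position=pos,
                type=kind,
                sequence=nseq,
                ambiguous_boundary=len(placements) > 1,
                placements=placements,
                partial="N" in nseq,
            )
        )
    events.sort(key=lambda e: (e.position, e.type, e.sequence))
    for a, b in zip(events, events[1:]):
        a_end = a.position + (len(a.sequence) if a.type == "del" else 0)
        if b.position - a_end < 3:
            a.compound = b.compound = True
    return events


def _ref_segment(refmap: ReferenceMap, start: int, end: int) -> str:
    """Reference bases at window positions start..end (1-based inclusive)."""
    if start < 1 or end > len(refmap.sequence):
        return ""
    return refmap.sequence[start - 1 : end]


def detect_tandem_duplication(event: IndelEvent, refmap: ReferenceMap) -> IndelEvent:
    """Retype an insertion as ``dupl`` when it copies the adjacent reference.

    Checks the segment immediately 3' of the (left-aligned) insertion point
    and, for non-canonical input, the segment immediately 5' of it; tandem
    arrays (the insert being k concatenated copies of the adjacent segment)
    report copy_number = k.
    """
    if event.type != "ins":
        return event
    s = event.sequence
    for period in [p for p in range(1, len(s) + 1) if len(s) % p == 0]:
        unit = s[:period]
        if unit * (len(s) // period) != s:
            continue
        if _ref_segment(refmap, event.position + 1, event.position + period) == unit:
            event.type = "dupl"
            event.copy_number = len(s) // period
            return event
        if _ref_segment(refmap, event.position - period + 1, event.position) == unit:
            event.type = "dupl"
            event.copy_number = len(s) // period
            return event
    return event


def classify_plant_insert(
    event: IndelEvent, allele_seq: str, refmap: ReferenceMap, max_tsd: int = 12
) -> IndelEvent:
    """Retype an insertion as ``plant_insert`` when a short direct repeat
    (3..max_tsd nt) of the flanking reference is duplicated across it.

    In the left-aligned representation a plant insert starts with a copy of
    the reference k-mer immediately 3' of the insertion point; the mirrored
    (right-aligned) pattern is also accepted.
    """
    if event.type != "ins":
        return event
    s = event.sequence
    for k in range(min(max_tsd, len(s) - 1), 2, -1):
        right = _ref_segment(refmap, event.position + 1, event.position + k)
        if right and s[:k] == right:
            event.type = "plant_insert"
            event.direct_repeat = right
            return event
        left = _ref_segment(refmap, event.position - k + 1, event.position)
        if left and s[-k:] == left:
            event.type = "plant_insert"
            event.direct_repeat = left
            return event
    return event


def classify_events(
    events: list[IndelEvent], allele_seq: str, refmap: ReferenceMap, max_tsd: int = 12
) -> list[IndelEvent]:
    """Run duplication then plant-insert classification on every insertion."""
    out = []
    for e in events:
        e = detect_tandem_duplication(e, refmap)
        e = classify_plant_insert(e, allele_seq, refmap, max_tsd=max_tsd)
        out.append(e)
    return out


def aggregate_catalog(events_by_allele: dict[str, list[IndelEvent]]) -> pd.DataFrame:
    """Merge per-allele events into a catalog table.

    Rows merge on (position, type, sequence, direct repeat); ``x`` counts the
    carrying alleles. Rows sharing a position get letter suffixes in their
    label (441, 449a, 449b, ...), mirroring the catalog convention.
    """
    merged: dict[tuple, IndelEvent] = {}
    for allele_id in sorted(events_by_allele):
        for e in events_by_allele[allele_id]:
            key = e.key()
            if key not in merged:
                merged[key] = IndelEvent(
                    position=e.position,
                    type=e.type,
                    sequence=e.sequence,
                    direct_repeat=e.direct_repeat,
                    copy_number=e.copy_number,
                    ambiguous_boundary=e.ambiguous_boundary,
                    placements=e.placements,
                    compound=e.compound,
                    partial=e.partial,
                )
            merged[key].alleles.append(allele_id)
    rows = sorted(merged.values(), key=lambda e: (e.position, e.type, e.sequence))
    by_pos: dict[int, int] = {}
    for e in rows:
        by_pos[e.position] = by_pos.get(e.position, 0) + 1
    seen: dict[int, int] = {}
    labels = []
    for e in rows:
        if by_pos[e.position] == 1:
            labels.append(str(e.position))
        else:
            labels.append(f"{e.position}{chr(ord('a') + seen.get(e.position, 0))}")
            seen[e.position] = seen.get(e.position, 0) + 1
    return pd.DataFrame(
        {
            "label": labels,
            "position": [e.position for e in rows],
            "type": [e.type for e in rows],
            "sequence": [e.sequence for e in rows],
            "direct_repeat": [e.direct_repeat for e in rows],
            "x": [len(e.alleles) for e in rows],
            "alleles": [",".join(e.alleles) for e in rows],
            "ambiguous_boundary": [e.ambiguous_boundary for e in rows],
            "compound": [e.compound for e in rows],
            "partial": [e.partial for e in rows],
        }
    )


def report_hypervariable_regions(
    catalog: pd.DataFrame, window: int = 15, min_events: int = 4
) -> list[tuple[int, int]]:
    """Maximal intervals where >= min_events distinct catalog rows fall in a
    sliding ``window``-nt window. Returns 1-based inclusive cT-DNA intervals.
    """
    if catalog.empty:
        return []
    positions = sorted(catalog["position"].tolist())
    qualifying: list[tuple[int, int]] = []
    for i, p in enumerate(positions):
        in_window = [q for q in positions if p <= q <= p + window - 1]
        if len(in_window) >= min_events:
            qualifying.append((p, max(in_window)))
    if not qualifying:
        return []
    merged = [qualifying[0]]
    for lo, hi in qualifying[1:]:
        if lo <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return merged


def regions_to_bed(regions: list[tuple[int, int]], name: str = "hypervariable") -> str:
    """BED (0-based half-open) text for region intervals (1-based inclusive)."""
    return "".join(f"ctdna\t{lo - 1}\t{hi}\t{name}\n" for lo, hi in regions)
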