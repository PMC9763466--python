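"""Seeded generator of synthetic cT-DNA populations.

Emulates the evolutionary structure of a single-copy cT-DNA locus fixed in an
allogamous diploid host:

* an ancestral locus whose terminal inverted repeats (IRs) start out
  identical, embedded in plant flanks with a target-site duplication;
* repeat divergence accumulated since insertion ("aging"), applied once at
  the population root with a fixed per-copy substitution count so the
  realized repeat divergence matches the configured molecular-clock load;
* a two-clade genealogy (groups A and B, each with two marker-defined
  subclades) whose substitutions avoid the repeats — the repeats carry
  exactly the insertion-age signal;
* an indel spectrum (deletions, insertions, tandem duplications, plant
  inserts flanked by short direct repeats) injected at canonical,
  left-aligned positions recorded in a machine-readable truth table;
* optionally one early-diverged lineage with the inverted-center
  rearrangement (central segment reverse-complemented plus two junction
  deletions), used downstream as the tree outgroup;
* error-bearing short reads at configurable coverage.

Every output is a pure function of the configuration (fixed seed implies
byte-identical FASTA/FASTQ/truth files).
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field

import numpy as np

from ._align import apply_indels, normalize_deletion, normalize_insertion, revcomp
from .reference import Interval, ReferenceMap, write_reference

# Locus geometry: 1-based inclusive coordinates on the full analysis window
# (200-nt flank + 5287-nt cT-DNA + 200-nt flank = 5687 nt); the left repeat
# starts at the first cT-DNA base.
CTDNA_LEN = 5287
FLANK_LEN = 200
CTDNA_SPAN = (FLANK_LEN + 1, FLANK_LEN + CTDNA_LEN)  # 201..5487
LEFT_IR = (201, 1148)
RIGHT_IR = (4528, 5487)
GENES = {"acs": (642, 1840), "susL": (2677, 3657), "rolB": (4218, 4532)}

# Indels are injected only in this central window (outside both repeats) so
# the repeats stay gap-free and carry a pure substitution clock.
_INDEL_REGION = (1160, 4510)

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class IndelTemplate:
    """One entry of the indel spectrum."""

    type: str  # del | ins | dupl | plant_insert
    length: tuple[int, int]  # inclusive range of event (core) lengths
    tsd_length: tuple[int, int] = (5, 10)  # plant inserts only
    weight: float = 1.0


def default_spectrum() -> list[IndelTemplate]:
    return [
        IndelTemplate("del", (3, 49), weight=0.45),
        IndelTemplate("ins", (3, 40), weight=0.20),
        IndelTemplate("dupl", (12, 20), weight=0.10),
        IndelTemplate("plant_insert", (20, 80), tsd_length=(5, 10), weight=0.25),
    ]


@dataclass
class SimulationConfig:
    seed: int = 0
    n_accessions: int = 20
    substitution_rate: float = 6.5e-9  # substitutions / site / year
    insertion_age: float = 15e6  # years
    allele_divergence_range: tuple[float, float] = (0.002, 0.073)
    indel_spectrum: list[IndelTemplate] = field(default_factory=default_spectrum)
    mean_private_indels: float = 1.2  # Poisson mean per allele
    p_rearranged_lineage: float = 1.0
    p_heterozygous: float = 0.58
    p_cross_clade: float = 0.5
    n_homoplasy: int = 0  # clade-A marker copies granted to random B alleles
    read_length: int = 150
    coverage: float = 30.0
    read_error_rate: float = 0.0
    tsd_len: int = 8  # target-site duplication of the locus insertion itself
    dating_convention: str = "paper"  # paper: d = mu*T; two_sided: d = 2*mu*T

    def __post_init__(self):
        for name in ("p_rearranged_lineage", "p_heterozygous", "p_cross_clade", "read_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.substitution_rate <= 0:
            raise ValueError("substitution_rate must be positive")
        if self.insertion_age < 0:
            raise ValueError("insertion_age must be non-negative")
        if self.n_accessions < 0:
            raise ValueError("n_accessions must be non-negative")
        lo, hi = self.allele_divergence_range
        if not 0 <= lo <= hi < 1:
            raise ValueError("allele_divergence_range must satisfy 0 <= lo <= hi < 1")
        if self.dating_convention not in ("paper", "two_sided"):
            raise ValueError("dating_convention must be 'paper' or 'two_sided'")

    @property
    def repeat_load(self) -> float:
        """Total expected repeat divergence implied by rate, age, convention."""
        d = self.substitution_rate * self.insertion_age
        return d if self.dating_convention == "paper" else 2.0 * d


@dataclass
class TruthIndel:
    position: int  # cT-DNA-local, last base before the modification, left-aligned
    type: str  # del | ins | dupl | plant_insert
    sequence: str
    direct_repeat: str = ""
    marker: str = ""  # non-empty for clade/subclade marker events

    @property
    def name(self) -> str:
        return self.marker or f"{self.type}{self.position}"


@dataclass
class AlleleTruth:
    allele_id: str
    accession: str
    sequence: str
    pre_indel_sequence: str | None  # post-substitution, reference-length
    indels: list[TruthIndel]
    structural_class: str = "standard"  # standard | inverted_center
    group: str = ""  # A | B | outgroup
    subgroup: str = ""


@dataclass
class TruthRecord:
    accession: str
    alleles: list[AlleleTruth]  # one entry = homozygous, two = heterozygous


@dataclass
class Population:
    records: list[TruthRecord]
    outgroup: TruthRecord | None
    markers: dict[str, TruthIndel]  # marker name -> canonical event
    config: SimulationConfig
    reference: ReferenceMap  # working reference: a present-day (aged) allele
    ancestor: ReferenceMap  # reconstruction with identical repeat copies

    def all_alleles(self, include_outgroup: bool = False) -> list[AlleleTruth]:
        out = [a for r in self.records for a in r.alleles]
        if include_outgroup and self.outgroup is not None:
            out.extend(self.outgroup.alleles)
        return out


# ---------------------------------------------------------------------------
# Ancestral locus
# ---------------------------------------------------------------------------


def _random_bases(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, n)]


def build_ancestral_ctdna(config: SimulationConfig) -> ReferenceMap:
    """Construct the ancestral locus with initially identical repeats.

    Geometry follows the reference coordinates (left repeat 201-1148, right
    repeat 4528-5487, genes acs/susL/rolB, 200-nt plant flanks). The right
    repeat carries the reverse complement of the left one on its last 948 nt
    (the two repeat annotations differ by 12 nt, reflecting the asymmetric
    arms of the source locus); the gene intervals hold open reading frames.
    The locus sits behind a target-site duplication of ``tsd_len`` nt.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    window = FLANK_LEN * 2 + CTDNA_LEN
    seq = _random_bases(rng, window)

    def idx(pos: int) -> int:  # window 1-based -> 0-based index
        return pos - 1

    # right IR: 12-nt pad + reverse complement of the left IR
    left = seq[idx(LEFT_IR[0]) : idx(LEFT_IR[1]) + 1]
    rc_left = np.frombuffer(revcomp(left.tobytes().decode()).encode(), dtype="S1")
    pad = RIGHT_IR[1] - RIGHT_IR[0] + 1 - len(rc_left)
    seq[idx(RIGHT_IR[0]) + pad : idx(RIGHT_IR[1]) + 1] = rc_left

    # target-site duplication: the right flank begins with a copy of the
    # left flank's last tsd_len bases (the pre-insertion target motif)
    if config.tsd_len:
        seq[idx(CTDNA_SPAN[1] + 1) : idx(CTDNA_SPAN[1] + 1) + config.tsd_len] = seq[
            idx(CTDNA_SPAN[0]) - config.tsd_len : idx(CTDNA_SPAN[0])
        ]

    # keep the canonical left-aligned placement of insertions after 3182
    # unambiguous for fixtures built from printed sequences ending in G
    if seq[idx(3182)] == b"G":
        seq[idx(3182)] = b"A"

    # open reading frames: remove in-frame stops; edits inside the left
    # repeat are mirrored into the right repeat to preserve their identity
    mirror_lo, mirror_hi = RIGHT_IR[0] + pad, RIGHT_IR[1]

    def set_base(pos: int, base: bytes) -> None:
        seq[idx(pos)] = base
        if LEFT_IR[0] <= pos <= LEFT_IR[1]:
            comp = revcomp(base.decode()).encode()
            seq[idx(mirror_hi - (pos - LEFT_IR[0]))] = comp
        elif mirror_lo <= pos <= mirror_hi:
            comp = revcomp(base.decode()).encode()
            seq[idx(LEFT_IR[0] + (mirror_hi - pos))] = comp

    for start, end in GENES.values():
        for cstart in range(start, end - 2, 3):
            codon = seq[idx(cstart) : idx(cstart) + 3].tobytes().decode()
            if codon in _STOPS:
                set_base(cstart + 2, b"C")  # TAC / TGC: never a stop

    return ReferenceMap(
        sequence=seq.tobytes().decode(),
        ctdna_span=Interval(*CTDNA_SPAN),
        left_ir=Interval(*LEFT_IR),
        right_ir=Interval(*RIGHT_IR),
        genes={name: Interval(*iv) for name, iv in GENES.items()},
        flank_len=FLANK_LEN,
    )


# ---------------------------------------------------------------------------
# Population evolution
# ---------------------------------------------------------------------------


def _aging_substitutions_per_copy(load: float) -> float:
    """Per-copy substitution fraction q such that the expected column
    mismatch rate between two independently aged copies equals ``load``.

    Columns mismatch when exactly one copy changed, or both changed to
    different bases: 2q(1-q) + (2/3)q^2 = load.
    """
    if load <= 0:
        return 0.0
    disc = 1.0 - 4.0 * load / 3.0
    if disc <= 0:
        raise ValueError(f"repeat load {load} too large for the substitution model")
    return 0.75 * (1.0 - math.sqrt(disc))


def _substitute(seq: np.ndarray, positions: np.ndarray, rng: np.random.Generator) -> None:
    """Mutate each position to one of the three other bases, in place."""
    for p in positions:
        cur = seq[p]
        choices = _BASES[_BASES != cur]
        seq[p] = choices[rng.integers(0, 3)]


def _fixed_count_substitute(seq: np.ndarray, lo: int, hi: int, q: float, rng) -> None:
    """Substitute a fixed round(q * length) sites within [lo, hi) (0-based)."""
    n = int(round(q * (hi - lo)))
    if n <= 0:
        return
    positions = lo + rng.choice(hi - lo, size=n, replace=False)
    _substitute(seq, positions, rng)


class _Evolver:
    """Holds shared state for one evolve_population run."""

    def __init__(self, ancestor: ReferenceMap, config: SimulationConfig):
        self.ref = ancestor
        self.cfg = config
        self.rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
        self.window = np.frombuffer(ancestor.sequence.encode(), dtype="S1").copy()

        d_lo, d_hi = config.allele_divergence_range
        ir_sites = ancestor.left_ir.length + ancestor.right_ir.length
        # lineage substitutions avoid the repeats; loads are rescaled so that
        # divergence measured over the whole window matches the configured
        # range (cross-clade pairs top out near the range maximum)
        scale = ancestor.window_len / (ancestor.window_len - ir_sites)
        x = 0.5 * d_hi * scale
        self.clade_load = 0.60 * x
        self.subclade_load = 0.10 * x
        self.private_load = (0.5 * d_lo * scale, 0.30 * x)

        # the working reference is a present-day allele: the root with the
        # insertion-age substitution load already on its repeats (real loci
        # are referenced against an extant, ~90%-identical-repeat allele,
        # which is also what makes repeat-region reads mappable)
        self.root = self._aged_root()
        self.refseq = self.root.tobytes().decode()
        self.work_ref = ReferenceMap(
            sequence=self.refseq,
            ctdna_span=ancestor.ctdna_span,
            left_ir=ancestor.left_ir,
            right_ir=ancestor.right_ir,
            genes=dict(ancestor.genes),
            flank_len=ancestor.flank_len,
        )
        self.markers = self._draw_markers()
        self.blocked = self._marker_guard_windows()
        self.sub_pool = self._substitution_pool()
        self.subclades = self._build_subclades()

    # -- setup ----------------------------------------------------------

    def _draw_markers(self) -> dict[str, TruthIndel]:
        """Clade/subclade marker indels at well-separated canonical positions."""
        if not self.cfg.indel_spectrum:
            return {}  # an empty spectrum disables all indels, markers included
        specs = [("A", "del", 7), ("A2", "del", 9), ("B1", "del", 5), ("B2", "plant_insert", 24)]
        markers: dict[str, TruthIndel] = {}
        used: list[tuple[int, int]] = []
        for label, kind, length in specs:
            for _ in range(500):
                ev = self._materialize_event(kind, length, tsd_len=6)
                if ev is None:
                    continue
                span = (ev.position - 60, ev.position + len(ev.sequence) + 60)
                if all(span[1] < lo or span[0] > hi for lo, hi in used):
                    ev.marker = f"{label}:{ev.type}{ev.position}"
                    markers[label] = ev
                    used.append(span)
                    break
            else:  # pragma: no cover - geometry makes this unreachable
                raise RuntimeError("could not place marker indels")
        return markers

    def _marker_guard_windows(self) -> list[tuple[int, int]]:
        """0-based window index ranges that substitutions must avoid."""
        out = []
        for ev in self.markers.values():
            lo = self.ref.seq_index(max(1, ev.position - 30))
            hi = self.ref.seq_index(min(len(self.refseq), ev.position + len(ev.sequence) + 30))
            out.append((lo, hi))
        return out

    def _substitution_pool(self) -> np.ndarray:
        ok = np.ones(self.ref.window_len, dtype=bool)
        for iv in (self.ref.left_ir, self.ref.right_ir):
            ok[self.ref.seq_index(iv.start) : self.ref.seq_index(iv.end) + 1] = False
        for lo, hi in self.blocked:
            ok[lo : hi + 1] = False
        return np.flatnonzero(ok)

    def _aged_root(self) -> np.ndarray:
        """Apply the insertion-age substitution load to both repeat copies.

        A fixed count per copy keeps the realized repeat divergence at the
        configured expectation (the clock signal is not re-randomized per
        lineage; all alleles inherit the same aged repeats, as real alleles
        share most of their post-insertion repeat history).
        """
        root = self.window.copy()
        q = _aging_substitutions_per_copy(self.cfg.repeat_load)
        for iv in (self.ref.left_ir, self.ref.right_ir):
            lo = self.ref.seq_index(iv.start)
            _fixed_count_substitute(root, lo, lo + iv.length, q, self.rng)
        return root

    def _lineage_subs(self, seq: np.ndarray, load: float) -> np.ndarray:
        out = seq.copy()
        n = self.rng.binomial(len(self.sub_pool), load)
        if n:
            positions = self.rng.choice(self.sub_pool, size=n, replace=False)
            _substitute(out, positions, self.rng)
        return out

    def _build_subclades(self) -> dict[str, dict]:
        """Two clades (A, B), two marker-defined subclades each."""
        clades = {g: self._lineage_subs(self.root, self.clade_load) for g in "AB"}
        out: dict[str, dict] = {}
        for name, clade, extra_markers in [
            ("A1", "A", []),
            ("A2", "A", ["A2"]),
            ("B1", "B", ["B1"]),
            ("B2", "B", ["B2"]),
        ]:
            markers = [m for m in (["A"] if clade == "A" else []) + extra_markers if m in self.markers]
            out[name] = {
                "group": clade,
                "seq": self._lineage_subs(clades[clade], self.subclade_load),
                "markers": [self.markers[m] for m in markers],
            }
        return out

    # -- indel machinery --------------------------------------------------

    def _materialize_event(
        self, kind: str, length: int, tsd_len: int = 6, background: str | None = None
    ) -> TruthIndel | None:
        """Draw one canonical (left-aligned) indel event on the reference.

        ``background`` (the allele's reference-length window string) is
        checked for substitutions inside the normalization window so the
        truth position stays canonical on the carrying allele; returns None
        if a clean placement was not found in this draw.
        """
        rng = self.rng
        pos = int(rng.integers(_INDEL_REGION[0], _INDEL_REGION[1]))
        ref = self.refseq
        if kind == "del":
            cpos, seq = normalize_deletion(ref, pos, length)
        elif kind == "ins":
            ins = _random_bases(rng, length).tobytes().decode()
            # forbid boundary-matching first/last bases: placement stays unique
            while ins[-1] == ref[pos - 1]:
                ins = ins[:-1] + _BASES[rng.integers(0, 4)].decode()
            while ins[0] == ref[pos]:
                ins = _BASES[rng.integers(0, 4)].decode() + ins[1:]
            cpos, seq = normalize_insertion(ref, pos, ins)
        elif kind == "dupl":
            if pos - length < _INDEL_REGION[0]:
                return None
            seq0 = ref[pos - length : pos]  # copy of the segment ending at pos
            cpos, seq = normalize_insertion(ref, pos, seq0)
        elif kind == "plant_insert":
            k = tsd_len
            target = ref[pos - k : pos]  # duplicated target motif
            core = _random_bases(rng, length).tobytes().decode()
            while core[-1] == ref[pos - k - 1]:
                core = core[:-1] + _BASES[rng.integers(0, 4)].decode()
            cpos, seq = normalize_insertion(ref, pos, core + target)
            if cpos != pos - k or not seq.startswith(target):
                return None  # target motif interacted with its context; redraw
            ev = TruthIndel(cpos, "plant_insert", seq, direct_repeat=target)
            return ev if self._window_clean(ev, background) else None
        else:  # pragma: no cover
            raise ValueError(kind)
        ev = TruthIndel(cpos, kind, seq)
        return ev if self._window_clean(ev, background) else None

    def _window_clean(self, ev: TruthIndel, background: str | None) -> bool:
        lo = max(1, ev.position - len(ev.sequence) - 5)
        hi = min(len(self.refseq), ev.position + 2 * len(ev.sequence) + 5)
        if not (_INDEL_REGION[0] - 80 <= ev.position <= _INDEL_REGION[1] + 80):
            return False
        if background is None:
            return True
        return background[lo - 1 : hi] == self.refseq[lo - 1 : hi]

    def _draw_private_indels(self, background: str, existing: list[TruthIndel]) -> list[TruthIndel]:
        templates = self.cfg.indel_spectrum
        if not templates:
            return []
        weights = np.array([t.weight for t in templates], dtype=float)
        weights /= weights.sum()
        n = self.rng.poisson(self.cfg.mean_private_indels)
        events: list[TruthIndel] = []
        spans = [
            (e.position - len(e.sequence) - 12, e.position + 2 * len(e.sequence) + 12)
            for e in existing
        ]
        for _ in range(n):
            for _attempt in range(200):
                t = templates[self.rng.choice(len(templates), p=weights)]
                length = int(self.rng.integers(t.length[0], t.length[1] + 1))
                tsd = int(self.rng.integers(t.tsd_length[0], t.tsd_length[1] + 1))
                ev = self._materialize_event(t.type, length, tsd_len=tsd, background=background)
                if ev is None:
                    continue
                span = (ev.position - len(ev.sequence) - 12, ev.position + 2 * len(ev.sequence) + 12)
                if all(span[1] < lo or span[0] > hi for lo, hi in spans):
                    events.append(ev)
                    spans.append(span)
                    break
        return events

    # -- allele / accession assembly --------------------------------------

    def _window_string(self, arr: np.ndarray) -> str:
        return arr.tobytes().decode()

    def apply_events(self, pre_indel_window: str, events: list[TruthIndel]) -> str:
        return apply_indels(
            pre_indel_window,
            [(e.position, "del" if e.type == "del" else "ins", e.sequence) for e in events],
        )

    def draw_allele_from(
        self, subclade: str, accession: str, index: str, avoid: list[TruthIndel] = ()
    ) -> AlleleTruth:
        """One allele from a subclade; ``avoid`` lists the partner haplotype's
        events so the two alleles of a diploid never carry colliding indels
        (colliding heterozygous gaps are not identifiable from short reads).
        """
        info = self.subclades[subclade]
        p_load = self.rng.uniform(*self.private_load)
        pre = self._window_string(self._lineage_subs(info["seq"], p_load))
        events = list(info["markers"])
        guard = events + list(avoid) + list(self.markers.values())
        events += self._draw_private_indels(pre, guard)
        events.sort(key=lambda e: e.position)
        seq = self.apply_events(pre, events)
        return AlleleTruth(
            allele_id=f"{accession}_{index}",
            accession=accession,
            sequence=seq,
            pre_indel_sequence=pre,
            indels=events,
            structural_class="standard",
            group=info["group"],
            subgroup=subclade,
        )

    def draw_outgroup(self) -> TruthRecord:
        """One early-diverged lineage with the inverted-center rearrangement."""
        load = 0.9 * (self.clade_load + self.subclade_load + self.private_load[1])
        pre = self._window_string(self._lineage_subs(self.root, load))
        c_lo = self.ref.left_ir.end  # 0-based start of the central segment
        c_hi = self.ref.right_ir.start - 1  # 0-based end (exclusive)
        central = revcomp(pre[c_lo:c_hi])
        del1 = int(self.rng.integers(30, 60))
        del2 = int(self.rng.integers(20, 50))
        seq = pre[:c_lo] + central[del1 : len(central) - del2] + pre[c_hi:]
        allele = AlleleTruth(
            allele_id="out0_un",
            accession="out0",
            sequence=seq,
            pre_indel_sequence=None,
            indels=[],
            structural_class="inverted_center",
            group="outgroup",
            subgroup="outgroup",
        )
        return TruthRecord(accession="out0", alleles=[allele])


def evolve_population(ancestor: ReferenceMap, config: SimulationConfig) -> Population:
    """Simulate the two-clade diploid population described by ``config``."""
    if config.n_accessions == 0:
        raise ValueError("degenerate config: zero accessions")
    ev = _Evolver(ancestor, config)
    records: list[TruthRecord] = []
    for i in range(config.n_accessions):
        acc = f"acc{i:03d}"
        if ev.rng.random() < config.p_heterozygous:
            if ev.rng.random() < config.p_cross_clade:
                s1 = ["A1", "A2"][ev.rng.integers(0, 2)]
                s2 = ["B1", "B2"][ev.rng.integers(0, 2)]
            else:
                group = "AB"[ev.rng.integers(0, 2)]
                s1 = [f"{group}1", f"{group}2"][ev.rng.integers(0, 2)]
                s2 = [f"{group}1", f"{group}2"][ev.rng.integers(0, 2)]
            first = ev.draw_allele_from(s1, acc, "1")
            alleles = [first, ev.draw_allele_from(s2, acc, "2", avoid=first.indels)]
        else:
            sub = list(ev.subclades)[ev.rng.integers(0, len(ev.subclades))]
            alleles = [ev.draw_allele_from(sub, acc, "un")]
        records.append(TruthRecord(accession=acc, alleles=alleles))

    # homoplasy: grant the clade-A marker to n random group-B alleles
    if config.n_homoplasy and "A" in ev.markers:
        marker = ev.markers["A"]
        b_alleles = [a for r in records for a in r.alleles if a.group == "B"]
        order = ev.rng.permutation(len(b_alleles))
        granted = 0
        for j in order:
            if granted >= config.n_homoplasy:
                break
            a = b_alleles[j]
            lo = max(1, marker.position - len(marker.sequence) - 5)
            hi = min(len(ev.refseq), marker.position + 2 * len(marker.sequence) + 5)
            clean = a.pre_indel_sequence[lo - 1 : hi] == ev.refseq[lo - 1 : hi]
            clash = any(
                abs(e.position - marker.position) < len(marker.sequence) + len(e.sequence) + 12
                for e in a.indels
            )
            if clean and not clash:
                a.indels = sorted(a.indels + [marker], key=lambda e: e.position)
                a.sequence = ev.apply_events(a.pre_indel_sequence, a.indels)
                granted += 1

    outgroup = ev.draw_outgroup() if ev.rng.random() < config.p_rearranged_lineage else None
    return Population(
        records=records,
        outgroup=outgroup,
        markers=ev.markers,
        config=config,
        reference=ev.work_ref,
        ancestor=ancestor,
    )


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------


def outer_context(config: SimulationConfig, length: int = 80) -> tuple[str, str]:
    """Shared plant-genome context just beyond the analysis window.

    Real reads extend past the locus window into the surrounding genome, so
    window-edge positions keep coverage; reads sampled across the boundary
    carry these context bases and are admitted by the recruitment identity
    threshold as long as the overhang is modest.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 404]))
    return (
        _random_bases(rng, length).tobytes().decode(),
        _random_bases(rng, length).tobytes().decode(),
    )


def reads_for_sequence(
    seq: str,
    coverage: float,
    read_length: int,
    error_rate: float,
    rng: np.random.Generator,
    name_prefix: str,
    pad: tuple[str, str] = ("", ""),
) -> list[tuple[str, str]]:
    """Uniform-start reads from both strands with per-base substitution errors.

    ``pad`` extends the template on either side (outer genomic context); the
    expected read count stays coverage * template_length / read_length.
    """
    seq = pad[0] + seq + pad[1]
    if read_length > len(seq):
        raise ValueError("read_length exceeds the template length")
    n = rng.poisson(coverage * len(seq) / read_length)
    arr = np.frombuffer(seq.encode(), dtype="S1")
    out = []
    starts = rng.integers(0, len(seq) - read_length + 1, size=n)
    strands = rng.random(n) < 0.5
    for i in range(n):
        read = arr[starts[i] : starts[i] + read_length].copy()
        if error_rate > 0:
            mask = np.flatnonzero(rng.random(read_length) < error_rate)
            _substitute(read, mask, rng)
        s = read.tobytes().decode()
        if strands[i]:
            s = revcomp(s)
        out.append((f"{name_prefix}:{i:05d}", s))
    return out


def generate_reads(
    record: TruthRecord, config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[list[tuple[str, str]], dict[str, str]]:
    """FASTQ-ready reads for one accession plus the read -> allele truth map.

    Read names carry no information about the allele of origin; traceability
    lives only in the returned mapping.
    """
    if config.coverage <= 0:
        raise ValueError("coverage must be positive")
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 303, _stable_hash(record.accession)])
        )
    reads: list[tuple[str, str]] = []
    origin: dict[str, str] = {}
    pad = outer_context(config)
    for allele in record.alleles:
        batch = reads_for_sequence(
            allele.sequence,
            config.coverage,
            config.read_length,
            config.read_error_rate,
            rng,
            name_prefix=f"{record.accession}",
            pad=pad,
        )
        for name, s in batch:
            name = f"{name}.{len(reads):06d}"
            reads.append((name, s))
            origin[name] = allele.allele_id
    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]
    return reads, origin


def _stable_hash(s: str) -> int:
    h = 0
    for ch in s:
        h = (h * 131 + ord(ch)) % (2**31 - 1)
    return h


# ---------------------------------------------------------------------------
# Fixture helpers and writers
# ---------------------------------------------------------------------------


def mutated_copy(seq: str, n_subs: int, rng: np.random.Generator, min_spacing: int = 25) -> str:
    """A copy of ``seq`` with n well-separated substitutions (test fixture).

    The spacing shrinks automatically when the requested density could not
    satisfy it (dense edits on short templates).
    """
    if n_subs == 0:
        return seq
    min_spacing = min(min_spacing, max(1, len(seq) // (3 * n_subs)))
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    chosen: list[int] = []
    while len(chosen) < n_subs:
        p = int(rng.integers(0, len(seq)))
        if all(abs(p - c) >= min_spacing for c in chosen):
            chosen.append(p)
    _substitute(arr, np.array(chosen), rng)
    return arr.tobytes().decode()


def empty_site_sequence(refmap: ReferenceMap, tsd_len: int) -> str:
    """The pre-insertion locus: flanks joined, one copy of the target motif."""
    f = refmap.flank_len
    return refmap.sequence[:f] + refmap.sequence[f + refmap.ctdna_span.length + tsd_len :]


def write_fasta(path, records: list[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def write_fastq(path, reads: list[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


def simulate_population(config: SimulationConfig) -> tuple[ReferenceMap, Population]:
    """Build the ancestor, evolve the population; returns (working reference,
    population). The working reference is the aged root allele (the analysis
    reference), not the repeat-identical ancestral reconstruction."""
    ancestor = build_ancestral_ctdna(config)
    pop = evolve_population(ancestor, config)
    return pop.reference, pop


def write_population(pop: Population, outdir) -> dict[str, str]:
    """Write reference, truth tables, allele FASTA and per-accession FASTQ."""
    os.makedirs(outdir, exist_ok=True)
    os.makedirs(os.path.join(outdir, "reads"), exist_ok=True)
    ref = pop.reference
    paths = {
        "reference_fasta": os.path.join(outdir, "reference.fa"),
        "features": os.path.join(outdir, "features.tsv"),
        "alleles": os.path.join(outdir, "true_alleles.fa"),
        "empty_site": os.path.join(outdir, "empty_site.fa"),
        "truth_alleles": os.path.join(outdir, "truth_alleles.tsv"),
        "truth_indels": os.path.join(outdir, "truth_indels.tsv"),
        "truth_reads": os.path.join(outdir, "truth_reads.tsv"),
        "config": os.path.join(outdir, "config.json"),
        "reads_dir": os.path.join(outdir, "reads"),
    }
    write_reference(ref, paths["reference_fasta"], paths["features"])
    write_fasta(paths["alleles"], [(a.allele_id, a.sequence) for a in pop.all_alleles(True)])
    write_fasta(paths["empty_site"], [("empty_site", empty_site_sequence(ref, pop.config.tsd_len))])
    if pop.outgroup is not None:
        paths["outgroup"] = os.path.join(outdir, "outgroup.fa")
        write_fasta(paths["outgroup"], [(a.allele_id, a.sequence) for a in pop.outgroup.alleles])

    with open(paths["truth_alleles"], "w") as fh:
        fh.write("accession\tallele_id\tgroup\tsubgroup\tstructural_class\tn_indels\n")
        for a in pop.all_alleles(True):
            fh.write(
                f"{a.accession}\t{a.allele_id}\t{a.group}\t{a.subgroup}\t"
                f"{a.structural_class}\t{len(a.indels)}\n"
            )
    with open(paths["truth_indels"], "w") as fh:
        fh.write("allele_id\tposition\ttype\tsequence\tdirect_repeat\tmarker\n")
        for a in pop.all_alleles(True):
            for e in a.indels:
                fh.write(
                    f"{a.allele_id}\t{e.position}\t{e.type}\t{e.sequence}\t"
                    f"{e.direct_repeat}\t{e.marker}\n"
                )
    with open(paths["truth_reads"], "w") as fh:
        fh.write("read\tallele_id\n")
        for rec in pop.records:
            reads, origin = generate_reads(rec, pop.config)
            write_fastq(os.path.join(paths["reads_dir"], f"{rec.accession}.fastq"), reads)
            for name, _ in reads:
                fh.write(f"{name}\t{origin[name]}\n")
    cfg = dataclasses.asdict(pop.config)
    with open(paths["config"], "w") as fh:
        json.dump(cfg, fh, indent=2, sort_keys=True, default=list)
        fh.write("\n")
    return paths
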