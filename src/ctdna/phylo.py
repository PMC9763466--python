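"""Allele tree construction and indel-marker concordance.

Phased alleles are aligned (mafft, with deterministic gap-column dropping in
place of manual indel curation), distances are Jukes-Cantor corrected
p-distances, the topology is neighbor joining with nonparametric bootstrap,
and the rooted tree is overlaid with indel-marker states: the two children
of the ingroup root define groups A and B, marker-defined clades define
subgroups, and marker carriers outside their home group are reported as
homoplasy exceptions.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj


@dataclass
class AlleleTree:
    tree: TreeNode  # rooted at the outgroup attachment node
    outgroup: str
    supports: dict[frozenset, float]  # ingroup-leaf bipartition -> support %
    newick: str
    leaves: list[str]


@dataclass
class ConcordanceReport:
    groups: dict[str, str]  # allele id -> A | B | outgroup
    subgroups: dict[str, str]  # allele id -> e.g. A2, B1 (or plain A/B)
    marker_homes: dict[str, str]  # marker -> home group
    exceptions: list[tuple[str, str]]  # (allele id, marker) homoplasy pairs
    marker_matrix: pd.DataFrame
    pair_spans: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# Multiple alignment
# ---------------------------------------------------------------------------


def align_alleles(sequences: dict[str, str], gap_threshold: float = 0.2) -> dict[str, str]:
    """Progressive multiple alignment with deterministic gap-column dropping.

    Runs mafft on the sequences (sorted by name for reproducibility), then
    removes every column whose gap fraction exceeds ``gap_threshold`` — the
    deterministic stand-in for manual removal of indel-rich columns before
    tree building.
    """
    if len(sequences) < 3:
        raise ValueError("multiple alignment needs at least 3 sequences")
    if shutil.which("mafft") is None:
        raise RuntimeError("mafft executable not found on PATH")
    with tempfile.TemporaryDirectory() as tmp:
        fa = Path(tmp) / "in.fa"
        with open(fa, "w") as fh:
            for name in sorted(sequences):
                fh.write(f">{name}\n{sequences[name]}\n")
        res = subprocess.run(
            ["mafft", "--retree", "2", "--maxiterate", "0", "--quiet", str(fa)],
            capture_output=True,
            text=True,
            check=True,
        )
    aligned: dict[str, list[str]] = {}
    name = None
    for line in res.stdout.splitlines():
        if line.startswith(">"):
            name = line[1:].split()[0]
            aligned[name] = []
        elif name:
            aligned[name].append(line.strip())
    msa = {k: "".join(v).upper() for k, v in aligned.items()}
    names = sorted(msa)
    mat = np.array([list(msa[n]) for n in names])
    gap_frac = np.mean(mat == "-", axis=0)
    keep = gap_frac <= gap_threshold
    mat = mat[:, keep]
    return {n: "".join(mat[i]) for i, n in enumerate(names)}


def _encode(msa: dict[str, str]) -> tuple[list[str], np.ndarray]:
    names = sorted(msa)
    mat = np.frombuffer("".join(msa[n] for n in names).encode(), dtype="S1")
    return names, mat.reshape(len(names), -1)


def jc_distance_matrix(msa: dict[str, str], columns: np.ndarray | None = None) -> DistanceMatrix:
    """Jukes-Cantor corrected p-distances, pairwise-deleting gap columns."""
    names, mat = _encode(msa)
    if columns is not None:
        mat = mat[:, columns]
    n = len(names)
    valid = (mat != b"-") & (mat != b"N")
    dm = np.zeros((n, n))
    matches = np.zeros((n, n))
    shared = valid.astype(np.float32) @ valid.astype(np.float32).T
    for base in (b"A", b"C", b"G", b"T"):
        hit = ((mat == base) & valid).astype(np.float32)
        matches += hit @ hit.T
    with np.errstate(divide="ignore", invalid="ignore"):
        p = 1.0 - matches / shared
    p = np.clip(np.nan_to_num(p), 0.0, 0.7499)
    dm = -0.75 * np.log(1.0 - 4.0 * p / 3.0)
    np.fill_diagonal(dm, 0.0)
    dm = (dm + dm.T) / 2.0
    return DistanceMatrix(dm, ids=names)


# ---------------------------------------------------------------------------
# Neighbor joining + bootstrap
# ---------------------------------------------------------------------------


def _bipartitions(tree: TreeNode, leaf_set: frozenset) -> set[frozenset]:
    """Ingroup bipartitions (smaller/canonical side) of an (un)rooted tree."""
    parts = set()
    for node in tree.non_tips():
        side = frozenset(t.name for t in node.tips()) & leaf_set
        if 1 < len(side) < len(leaf_set) - 1:
            other = leaf_set - side
            parts.add(min(side, other, key=lambda s: (len(s), sorted(s))))
    return parts


def _ladderize(node: TreeNode) -> None:
    for child in node.children:
        _ladderize(child)
    node.children.sort(key=lambda c: (c.count(tips=True), min(t.name for t in c.tips()) if not c.is_tip() else c.name))
    for i, c in enumerate(node.children):  # re-link after sort
        c.parent = node


def build_tree(
    msa: dict[str, str], outgroup: str, n_bootstrap: int = 200, seed: int = 0
) -> AlleleTree:
    """Neighbor-joining tree with nonparametric bootstrap, outgroup-rooted."""
    if outgroup not in msa:
        raise ValueError(f"outgroup {outgroup!r} not among the aligned sequences")
    dm = jc_distance_matrix(msa)
    tree = nj(dm)
    og = tree.find(outgroup)
    rooted = tree.root_at(og.parent) if og.parent is not None else tree
    leaf_set = frozenset(n for n in msa if n != outgroup)
    main_parts = _bipartitions(rooted, leaf_set)

    rng = np.random.default_rng(seed)
    ncol = len(next(iter(msa.values())))
    counts = {p: 0 for p in main_parts}
    for _ in range(n_bootstrap):
        cols = rng.integers(0, ncol, size=ncol)
        bdm = jc_distance_matrix(msa, columns=cols)
        bparts = _bipartitions(nj(bdm), leaf_set)
        for p in main_parts:
            if p in bparts:
                counts[p] += 1
    supports = {p: 100.0 * c / max(1, n_bootstrap) for p, c in counts.items()}

    _ladderize(rooted)
    for node in rooted.non_tips():
        side = frozenset(t.name for t in node.tips()) & leaf_set
        key = min(side, leaf_set - side, key=lambda s: (len(s), sorted(s)))
        if key in supports:
            node.name = f"{supports[key]:.0f}"
    newick = str(rooted).strip()
    return AlleleTree(rooted, outgroup, supports, newick, sorted(msa))


# ---------------------------------------------------------------------------
# Group assignment and pair spans
# ---------------------------------------------------------------------------


def marker_matrix_from_catalog(catalog: pd.DataFrame, allele_ids: list[str], min_count: int = 3) -> pd.DataFrame:
    """Allele x marker presence matrix from catalog rows carried by >= min_count alleles."""
    rows = catalog[catalog["x"] >= min_count]
    data = {}
    for _, row in rows.iterrows():
        marker = f"{row['type']}{row['label']}"
        carriers = set(row["alleles"].split(","))
        data[marker] = [a in carriers for a in allele_ids]
    return pd.DataFrame(data, index=allele_ids, dtype=bool)


def assign_groups(tree: AlleleTree, markers: pd.DataFrame) -> ConcordanceReport:
    """Label the two ingroup root clades A/B and derive marker subgroups.

    Group A is the root clade richer (by carrier fraction) in the most
    prevalent marker, echoing the convention that the most frequent marker
    deletion characterizes group A; ties fall back to the clade holding the
    lexicographically smallest allele id. Each marker's home group is its
    majority group; carriers in the other group are homoplasy exceptions.
    """
    root = tree.tree
    ingroup_children = [c for c in root.children if tree.outgroup not in {t.name for t in c.tips()}]
    clades = []
    for child in ingroup_children:
        clades.append(sorted(t.name for t in child.tips()))
    if len(clades) != 2:
        # outgroup attached to a >2-ary root: treat the largest two clades
        clades = sorted(clades, key=len, reverse=True)[:2]
    if len(clades) < 2:
        raise ValueError("tree root does not define two ingroup clades")

    prevalent = None
    if not markers.empty:
        prevalent = markers.sum().idxmax()
    if prevalent is not None and markers[prevalent].any():
        fracs = [
            markers.loc[[a for a in clade if a in markers.index], prevalent].mean()
            for clade in clades
        ]
        if fracs[1] > fracs[0]:
            clades = clades[::-1]
    elif min(clades[1]) < min(clades[0]):
        clades = clades[::-1]

    groups = {a: "A" for a in clades[0]}
    groups.update({a: "B" for a in clades[1]})
    groups[tree.outgroup] = "outgroup"

    marker_homes: dict[str, str] = {}
    exceptions: list[tuple[str, str]] = []
    subgroup_index = {"A": 0, "B": 0}
    subgroups = dict(groups)
    # most prevalent marker first: broader clades get lower subgroup numbers
    for marker in markers.sum().sort_values(ascending=False).index if not markers.empty else []:
        carriers = [a for a in markers.index[markers[marker]] if a in groups]
        if not carriers:
            continue
        in_a = sum(1 for a in carriers if groups[a] == "A")
        home = "A" if in_a * 2 >= len(carriers) else "B"
        marker_homes[marker] = home
        for a in carriers:
            if groups.get(a) not in (home, "outgroup") and groups.get(a) is not None:
                exceptions.append((a, marker))
        home_carriers = [a for a in carriers if groups[a] == home]
        if home_carriers and len(home_carriers) < len(clades[0 if home == "A" else 1]):
            subgroup_index[home] += 1
            label = f"{home}{subgroup_index[home]}"
            for a in home_carriers:
                subgroups[a] = label
    return ConcordanceReport(
        groups=groups,
        subgroups=subgroups,
        marker_homes=marker_homes,
        exceptions=sorted(exceptions),
        marker_matrix=markers,
    )


def pair_spans(report: ConcordanceReport, alleles_by_accession: dict[str, list[str]]) -> pd.DataFrame:
    """Group labels of each heterozygous accession's allele pair."""
    rows = []
    for acc in sorted(alleles_by_accession):
        ids = [a for a in alleles_by_accession[acc] if a in report.groups]
        if len(ids) != 2:
            continue
        g1, g2 = sorted(report.groups[a] for a in ids)
        rows.append({"accession": acc, "group_1": g1, "group_2": g2, "cross_group": g1 != g2})
    df = pd.DataFrame(rows, columns=["accession", "group_1", "group_2", "cross_group"])
    report.pair_spans = df
    return df
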