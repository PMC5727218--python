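"""Haplotype calling from aligned sequences and minimum-spanning networks.

An alignment over {A, C, G, T, N, -} is reduced to a table of polymorphic
characters: substitution columns with at least two observed bases become
SNP characters, and each distinct maximal gap run (identical start/end
across the sequences that carry it) becomes ONE binary presence/absence
indel character — so a multi-base insertion/deletion counts as a single
mutational event.  N is treated as missing and matches any state when
sequences are collapsed into haplotypes.

The haplotype network is the minimum-spanning network: the graph containing
every edge that occurs in at least one minimum spanning tree of the
pairwise character-distance graph (ties retained).  This reproduces
median-joining topologies for low-homoplasy data without median vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from nichepop.synthetic_data import Alignment

MISSING = "?"

__all__ = [
    "CharacterTable",
    "HaplotypeSet",
    "call_characters",
    "collapse_haplotypes",
    "build_network",
    "read_fasta_alignment",
    "write_fasta_alignment",
]


def read_fasta_alignment(path: str | Path) -> Alignment:
    """Read an aligned FASTA file (equal-length sequences required)."""
    from Bio import SeqIO

    ids, seqs = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        seqs.append(str(rec.seq).upper())
    return Alignment(ids, seqs)


def write_fasta_alignment(aln: Alignment, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for sid, seq in zip(aln.ids, aln.seqs):
            fh.write(f">{sid}\n{seq}\n")


@dataclass
class CharacterTable:
    """Polymorphic characters per sequence.

    ``states`` is (n_sequences, n_characters) of single-character strings;
    SNP characters hold the base, indel characters "0"/"1" (absent/present),
    and ``?`` marks missing.  ``characters`` describes each column:
    ``{"kind": "snp", "position": int}`` or
    ``{"kind": "indel", "start": int, "end": int}`` (end exclusive).
    """

    ids: list[str]
    states: np.ndarray
    characters: list[dict]

    @property
    def n_characters(self) -> int:
        return self.states.shape[1]


def _gap_runs(seq: str) -> list[tuple[int, int]]:
    """Maximal runs of '-' as (start, end) half-open intervals."""
    runs = []
    start = None
    for i, ch in enumerate(seq):
        if ch == "-" and start is None:
            start = i
        elif ch != "-" and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(seq)))
    return runs


def call_characters(aln: Alignment) -> CharacterTable:
    """Extract SNP and indel characters from an alignment.

    Substitution columns with >= 2 distinct bases (among A/C/G/T; gaps and
    N ignored) become SNP characters.  Each distinct maximal gap-run extent
    becomes one binary indel character.  The result is independent of the
    order of input sequences (characters are sorted by position).
    """
    if len({len(s) for s in aln.seqs}) > 1:
        raise ValueError("ragged alignment")
    n = len(aln.seqs)
    length = aln.length
    allowed = set("ACGTN-")
    for sid, s in zip(aln.ids, aln.seqs):
        bad = set(s) - allowed
        if bad:
            raise ValueError(f"sequence {sid!r} has invalid symbols {sorted(bad)}")

    # indel characters: distinct maximal gap-run extents
    run_members: dict[tuple[int, int], set[int]] = {}
    for i, s in enumerate(aln.seqs):
        for run in _gap_runs(s):
            run_members.setdefault(run, set()).add(i)
    indel_runs = sorted(run_members)

    columns: list[np.ndarray] = []
    chars: list[dict] = []

    seq_arr = np.array([list(s) for s in aln.seqs]) if n else np.empty((0, length), dtype="<U1")
    for j in range(length):
        col = seq_arr[:, j] if n else np.array([])
        bases = set(col) & set("ACGT")
        if len(bases) >= 2:
            states = np.where(np.isin(col, list("ACGT")), col, MISSING)
            columns.append(states)
            chars.append({"kind": "snp", "position": j})

    for run in indel_runs:
        states = np.array(
            ["1" if i in run_members[run] else "0" for i in range(n)], dtype="<U1"
        )
        # N spanning the run means the gap state is unknowable
        for i in range(n):
            if states[i] == "0" and "N" in aln.seqs[i][run[0]:run[1]]:
                states[i] = MISSING
        columns.append(states)
        chars.append({"kind": "indel", "start": run[0], "end": run[1]})

    states = (
        np.column_stack(columns) if columns else np.empty((n, 0), dtype="<U1")
    )
    return CharacterTable(list(aln.ids), states, chars)


@dataclass
class HaplotypeSet:
    """Distinct haplotypes with counts and membership.

    ``states`` is (n_haplotypes, n_characters); ``members`` maps haplotype
    index to the sequence ids collapsed into it; ``ambiguous`` records
    sequences whose assignment relied on the missing-matches-anything rule.
    """

    states: np.ndarray
    counts: np.ndarray
    members: list[list[str]]
    characters: list[dict]
    ambiguous: list[dict] = field(default_factory=list)

    @property
    def n_haplotypes(self) -> int:
        return self.states.shape[0]

    def labels(self) -> list[str]:
        """Reporting labels: 'major' if carried by >1 sequence else 'unique'."""
        return ["major" if c > 1 else "unique" for c in self.counts]


def _compatible(a: np.ndarray, b: np.ndarray) -> bool:
    """True if states match wherever both are non-missing."""
    both = (a != MISSING) & (b != MISSING)
    return bool((a[both] == b[both]).all())


def collapse_haplotypes(table: CharacterTable) -> HaplotypeSet:
    """Group sequences identical across all characters into haplotypes.

    Missing states match anything.  Sequences without missing data define
    the haplotypes; a sequence with missing data joins the unique compatible
    haplotype, or — if several are compatible — the one with the most
    members (flagged in ``ambiguous``), or founds a new haplotype if none
    is compatible.
    """
    n = len(table.ids)
    hap_states: list[np.ndarray] = []
    members: list[list[str]] = []
    ambiguous: list[dict] = []

    complete = [i for i in range(n) if MISSING not in table.states[i]]
    incomplete = [i for i in range(n) if i not in set(complete)]
    for i in complete:
        row = table.states[i]
        for h, hs in enumerate(hap_states):
            if (hs == row).all():
                members[h].append(table.ids[i])
                break
        else:
            hap_states.append(row.copy())
            members.append([table.ids[i]])

    for i in incomplete:
        row = table.states[i]
        compat = [h for h, hs in enumerate(hap_states) if _compatible(hs, row)]
        if len(compat) == 1:
            h = compat[0]
            members[h].append(table.ids[i])
            ambiguous.append({"id": table.ids[i], "assigned": h, "candidates": compat})
        elif compat:
            sizes = [len(members[h]) for h in compat]
            h = compat[int(np.argmax(sizes))]
            members[h].append(table.ids[i])
            ambiguous.append({"id": table.ids[i], "assigned": h, "candidates": compat})
        else:
            hap_states.append(row.copy())
            members.append([table.ids[i]])

    states = (
        np.vstack(hap_states) if hap_states else np.empty((0, table.n_characters), dtype="<U1")
    )
    counts = np.array([len(m) for m in members], dtype=int)
    return HaplotypeSet(states, counts, members, list(table.characters), ambiguous)


def character_distance(a: np.ndarray, b: np.ndarray) -> int:
    """Number of characters differing (both states known); indel = 1 step."""
    both = (a != MISSING) & (b != MISSING)
    return int((a[both] != b[both]).sum())


def build_network(h: HaplotypeSet) -> nx.Graph:
    """Minimum-spanning network over haplotype character distances.

    Contains every edge occurring in at least one minimum spanning tree of
    the complete pairwise-distance graph (so equal-weight alternatives are
    all retained).  Nodes carry ``count`` and ``members``; edges carry the
    integer ``distance``.
    """
    k = h.n_haplotypes
    g = nx.Graph()
    for i in range(k):
        g.add_node(i, count=int(h.counts[i]), members=list(h.members[i]),
                   label=h.labels()[i])
    if k <= 1:
        return g
    dist = np.zeros((k, k), dtype=int)
    for i in range(k):
        for j in range(i + 1, k):
            dist[i, j] = dist[j, i] = character_distance(h.states[i], h.states[j])

    # Kruskal by weight class: an edge of weight w belongs to some MST iff
    # its endpoints are in different components of the graph of all edges
    # with weight strictly below w.
    parent = list(range(k))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    edges = sorted(
        ((dist[i, j], i, j) for i in range(k) for j in range(i + 1, k)), key=lambda e: e[0]
    )
    pos = 0
    while pos < len(edges):
        w = edges[pos][0]
        batch = []
        while pos < len(edges) and edges[pos][0] == w:
            batch.append(edges[pos])
            pos += 1
        keep = [(i, j) for _, i, j in batch if find(i) != find(j)]
        for i, j in keep:
            g.add_edge(i, j, distance=int(dist[i, j]))
        for i, j in keep:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[ri] = rj
    return g


def write_network(g: nx.Graph, graphml_path: str | Path, edgelist_path: str | Path) -> None:
    """Write the network as GraphML and a simple edge-list TSV."""
    g2 = g.copy()
    for _, data in g2.nodes(data=True):
        data["members"] = ",".join(data.get("members", []))
    nx.write_graphml(g2, str(graphml_path))
    with Path(edgelist_path).open("w") as fh:
        fh.write("from\tto\tdistance\n")
        for u, v, data in g.edges(data=True):
            fh.write(f"{u}\t{v}\t{data['distance']}\n")
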