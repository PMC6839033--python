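"""Readers and writers for the external formats the pipeline touches.

FASTA proteomes, two-column TSV edge lists (physical protein–protein
interactions), protein→term annotation tables with a term→(sub)cluster
grouping, and Newick trees.  All identifier joining downstream assumes the
identifiers in these files are already consistent with each other; no ID
mapping is attempted here.

Coordinates reported by the scanners are 0-based half-open throughout the
package and converted to 1-based only in human-readable reports.
"""

from __future__ import annotations

import gzip
import io
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import networkx as nx
from Bio import SeqIO
from skbio import TreeNode

from .alphabet import AA_INDEX

logger = logging.getLogger(__name__)

SanitizePolicy = Literal["drop_noncanonical", "reject"]

# Characters that may legitimately appear in FASTA protein records but are
# outside the canonical 20-letter alphabet: ambiguity codes, rare residues,
# stops and gaps.
_NONCANONICAL = set("XUBZJO*-.")


@dataclass(frozen=True)
class Proteome:
    """A species' set of identified protein sequences.

    ``records`` is an ordered list of ``(protein_id, sequence)`` pairs with
    unique ids and non-empty sequences over the canonical alphabet.

    ``breaks`` records, per protein, the positions (0-based, in sanitized
    coordinates) where one or more non-canonical characters were removed
    during sanitization.  A removed character terminates a homopolymer run:
    the scanners treat these positions as hard boundaries, so deletion never
    fabricates a repeat that was absent from the raw sequence.
    """

    species_id: str
    records: tuple[tuple[str, str], ...]
    breaks: tuple[tuple[str, tuple[int, ...]], ...] = ()

    def __post_init__(self) -> None:
        ids = [pid for pid, _ in self.records]
        if len(set(ids)) != len(ids):
            seen: set[str] = set()
            for pid in ids:
                if pid in seen:
                    raise ValueError(f"duplicate protein id: {pid!r}")
                seen.add(pid)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(pid for pid, _ in self.records)

    @property
    def sequences(self) -> tuple[str, ...]:
        return tuple(seq for _, seq in self.records)

    def breaks_of(self, pid: str) -> tuple[int, ...]:
        for p, b in self.breaks:
            if p == pid:
                return b
        return ()

    def segments(self, pid: str, sequence: str) -> list[str]:
        """The sequence split at its run-break positions."""
        cuts = self.breaks_of(pid)
        if not cuts:
            return [sequence]
        out, prev = [], 0
        for c in cuts:
            out.append(sequence[prev:c])
            prev = c
        out.append(sequence[prev:])
        return [s for s in out if s]


@dataclass
class AnnotationSet:
    """Protein→term assignments plus a term→(cluster, subcluster) grouping.

    Protein sets may overlap across terms.  ``pool_cluster`` /
    ``pool_subcluster`` return the union of the protein sets of all terms in
    one semantic (sub)cluster — the unit at which enrichment is screened.
    """

    assignments: dict[str, set[str]]
    grouping: dict[str, tuple[str, str | None]] = field(default_factory=dict)

    def pool_cluster(self, cluster_id: str) -> set[str]:
        pooled: set[str] = set()
        for term, (cl, _sub) in self.grouping.items():
            if cl == cluster_id and term in self.assignments:
                pooled |= self.assignments[term]
        return pooled

    def pool_subcluster(self, subcluster_id: str) -> set[str]:
        pooled: set[str] = set()
        for term, (_cl, sub) in self.grouping.items():
            if sub == subcluster_id and term in self.assignments:
                pooled |= self.assignments[term]
        return pooled

    @property
    def clusters(self) -> tuple[str, ...]:
        return tuple(sorted({cl for cl, _ in self.grouping.values()}))

    @property
    def subclusters(self) -> tuple[str, ...]:
        return tuple(
            sorted({sub for _, sub in self.grouping.values() if sub is not None})
        )


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="ascii")
    return open(path, encoding="ascii")


def _sanitize(
    seq: str, policy: SanitizePolicy, pid: str
) -> tuple[str, tuple[int, ...]]:
    """Upper-case and enforce the canonical alphabet.

    ``drop_noncanonical`` removes offending characters and returns the
    positions (sanitized coordinates) where a removal occurred strictly
    inside the sequence.  Scanners treat these positions as run boundaries,
    so deleting an interrupting character never merges its two flanks into
    a single longer homopolymer run.
    """
    seq = seq.upper()
    if all(c in AA_INDEX for c in seq):
        return seq, ()
    if policy == "reject":
        bad = sorted({c for c in seq if c not in AA_INDEX})
        raise ValueError(f"non-canonical characters {bad} in record {pid!r}")
    kept: list[str] = []
    cuts: set[int] = set()
    for c in seq:
        if c in AA_INDEX:
            kept.append(c)
        elif kept:  # a removal at position 0 breaks nothing
            cuts.add(len(kept))
    clean = "".join(kept)
    return clean, tuple(sorted(p for p in cuts if 0 < p < len(clean)))


def extract_id(header_token: str, id_regex: str | None = None) -> str:
    """Protein id from a FASTA header token.

    Default: the token itself (first whitespace-delimited word).  An
    ``id_regex`` with one capture group can pull a bare accession out of
    UniProt-style ``sp|ACC|NAME`` headers so that interactome/annotation
    joins see the same identifiers.
    """
    if id_regex is None:
        return header_token
    m = re.search(id_regex, header_token)
    if m is None:
        raise ValueError(f"id_regex {id_regex!r} did not match {header_token!r}")
    return m.group(1)


def read_fasta(
    path: str | Path,
    species_id: str | None = None,
    sanitize_policy: SanitizePolicy = "drop_noncanonical",
    id_regex: str | None = None,
) -> Proteome:
    """Read a proteome from (optionally gzipped) FASTA.

    The protein id is the first whitespace-delimited header token (or the
    capture group of *id_regex*).  Sequences are upper-cased; characters
    outside the canonical alphabet are handled per *sanitize_policy*.
    Raises on empty files, duplicate ids, and empty sequences.
    """
    path = Path(path)
    records: list[tuple[str, str]] = []
    breaks: list[tuple[str, tuple[int, ...]]] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            token = rec.id  # Biopython: first whitespace-delimited token
            pid = extract_id(token, id_regex)
            if pid in seen:
                raise ValueError(f"duplicate protein id {pid!r} in {path}")
            seen.add(pid)
            seq, cuts = _sanitize(str(rec.seq), sanitize_policy, pid)
            if not seq:
                raise ValueError(f"record {pid!r} in {path} has an empty sequence")
            records.append((pid, seq))
            if cuts:
                breaks.append((pid, cuts))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return Proteome(species_id or path.stem, tuple(records), tuple(breaks))


def write_fasta(proteome: Proteome, path: str | Path, width: int = 60) -> None:
    with open(path, "w", encoding="ascii") as fh:
        for pid, seq in proteome.records:
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_edge_list(path: str | Path) -> nx.Graph:
    """Undirected interaction network from a ≥2-column TSV of id pairs.

    Duplicate edges (in either orientation) are collapsed; self-loops are
    dropped with a logged count.  The number of dropped self-loops is also
    stored on the graph as ``G.graph["n_self_loops_dropped"]``.
    """
    g = nx.Graph()
    n_self = 0
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 2 or not parts[0] or not parts[1]:
                raise ValueError(f"{path}: malformed edge line {lineno}: {line!r}")
            a, b = parts[0], parts[1]
            if a == b:
                n_self += 1
                g.add_node(a)
                continue
            g.add_edge(a, b)
    if n_self:
        logger.info("dropped %d self-loop(s) while reading %s", n_self, path)
    g.graph["n_self_loops_dropped"] = n_self
    return g


def read_annotation_table(
    assign_path: str | Path,
    grouping_path: str | Path | None = None,
    strict: bool = False,
) -> AnnotationSet:
    """Protein→term table plus optional term→(sub)cluster grouping.

    *assign_path*: two-column TSV ``protein_id<TAB>term_id`` (set semantics:
    repeated rows count once).  *grouping_path*: TSV
    ``term_id<TAB>cluster_id[<TAB>subcluster_id]``.  A term present in the
    assignments but absent from the grouping is a warning (``strict=False``)
    or an error (``strict=True``).
    """
    assignments: dict[str, set[str]] = {}
    with _open_text(assign_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not parts[0] or not parts[1]:
                raise ValueError(
                    f"{assign_path}: malformed annotation line {lineno}: {line!r}"
                )
            protein, term = parts[0], parts[1]
            assignments.setdefault(term, set()).add(protein)

    grouping: dict[str, tuple[str, str | None]] = {}
    if grouping_path is not None:
        with _open_text(grouping_path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2 or not parts[0] or not parts[1]:
                    raise ValueError(
                        f"{grouping_path}: malformed grouping line {lineno}: {line!r}"
                    )
                term, cluster = parts[0], parts[1]
                sub = parts[2] if len(parts) > 2 and parts[2] else None
                grouping[term] = (cluster, sub)
        missing = sorted(set(assignments) - set(grouping))
        if missing:
            msg = f"{len(missing)} assigned term(s) missing from grouping: {missing[:5]}"
            if strict:
                raise ValueError(msg)
            logger.warning(msg)
    elif strict:
        raise ValueError("strict=True requires a grouping table")

    return AnnotationSet(assignments=assignments, grouping=grouping)


# ---------------------------------------------------------------------------
# Newick / unrooted topologies
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TreeTopology:
    """An unrooted, leaf-labeled tree topology.

    Stored as the leaf-name set plus the set of nontrivial bipartitions
    (splits), each canonicalized as the frozenset of the side *not*
    containing the lexicographically smallest leaf.  Branch lengths are
    ignored.  The originating ``skbio.TreeNode`` is kept for Newick output.
    """

    leaves: frozenset[str]
    splits: frozenset[frozenset[str]]
    _tree: TreeNode | None = field(default=None, compare=False, hash=False, repr=False)

    @classmethod
    def from_treenode(cls, tree: TreeNode) -> "TreeTopology":
        tree = tree.copy()
        names = [t.name for t in tree.tips()]
        if any(n is None for n in names):
            raise ValueError("all leaves must be labeled")
        if len(set(names)) != len(names):
            raise ValueError("leaf labels must be unique")
        leaves = frozenset(names)
        if len(tree.children) == 2 and len(names) > 2:
            tree.unroot()  # suppress a rooted input's degree-2 root
        anchor = min(leaves)
        splits: set[frozenset[str]] = set()
        for node in tree.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            if 1 < len(side) < len(leaves) - 1:
                if anchor in side:
                    side = leaves - side
                splits.add(side)
        return cls(frozenset(leaves), frozenset(splits), tree)

    @classmethod
    def from_newick(cls, newick: str) -> "TreeTopology":
        return cls.from_treenode(TreeNode.read(io.StringIO(newick)))

    def to_newick(self) -> str:
        if self._tree is None:
            raise ValueError("topology has no attached tree structure")
        buf = io.StringIO()
        self._tree.write(buf)
        return buf.getvalue().strip()


def read_newick(path: str | Path) -> TreeTopology:
    """Parse a Newick file into an unrooted :class:`TreeTopology`."""
    with _open_text(path) as fh:
        text = fh.read().strip()
    if not text:
        raise ValueError(f"{path}: empty Newick file")
    try:
        return TreeTopology.from_newick(text)
    except Exception as exc:  # skbio raises several parse error types
        raise ValueError(f"{path}: Newick parse error: {exc}") from exc


def write_newick(tree: TreeTopology, path: str | Path) -> None:
    Path(path).write_text(tree.to_newick() + "\n", encoding="ascii")
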