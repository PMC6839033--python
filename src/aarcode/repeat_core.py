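"""Homopolymeric-run detection and per-proteome repeat profiles.

An AAR (homopolymeric amino-acid repeat) is a maximal contiguous run of one
amino acid of length >= ``min_len`` (default 4).  All downstream statistics
are presence/absence per protein: a protein either contains at least one
qualifying run of X or it does not, regardless of how many stretches it has
or how long they are.

Two detection paths exist and are tested for equality: a per-sequence
linear scan (`scan_runs`, the reference semantics) and a vectorized path
over a concatenated byte array (`presence_matrix`) used for large
simulated proteomes.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import groupby
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .alphabet import AA_INDEX, AMINO_ACIDS, N_AA, _CODE_TO_INDEX, encode
from .seqio import Proteome

DEFAULT_MIN_LEN = 4


@dataclass(frozen=True)
class Run:
    """A maximal homopolymeric run: letter, 0-based start, length."""

    amino_acid: str
    start: int
    length: int

    @property
    def end(self) -> int:
        """0-based exclusive end."""
        return self.start + self.length


def scan_runs(sequence: str, min_len: int = DEFAULT_MIN_LEN) -> list[Run]:
    """All maximal runs of identical residues with length >= *min_len*.

    Runs are strictly contiguous (no mismatches tolerated) and reported
    left to right.  The sequence must already be sanitized to the canonical
    alphabet; non-canonical characters raise.
    """
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    runs: list[Run] = []
    pos = 0
    for aa, grp in groupby(sequence):
        if aa not in AA_INDEX:
            raise ValueError(f"non-canonical character {aa!r} at position {pos}")
        length = sum(1 for _ in grp)
        if length >= min_len:
            runs.append(Run(aa, pos, length))
        pos += length
    return runs


def aar_presence(sequence: str, min_len: int = DEFAULT_MIN_LEN) -> set[str]:
    """Set of amino acids with at least one qualifying run in *sequence*.

    Multiple stretches of one amino acid contribute a single membership.
    """
    return {r.amino_acid for r in scan_runs(sequence, min_len)}


# ---------------------------------------------------------------------------
# Vectorized presence detection
# ---------------------------------------------------------------------------

_SEP = ord("\n")      # between-protein separator
_BREAK = ord("\t")    # intra-protein run break (removed non-canonical char)


def _concat_codes(sequences: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    """Concatenate sequences with a separator byte; return (codes, protein_idx).

    Sequences may contain tab characters marking sanitization run breaks;
    they block run/substring matches without starting a new protein.
    """
    blob = "\n".join(sequences)
    codes = encode(blob)
    protein_idx = np.cumsum(codes == _SEP) - (codes == _SEP)
    return codes, protein_idx


def presence_matrix(
    sequences: Sequence[str], min_len: int = DEFAULT_MIN_LEN
) -> np.ndarray:
    """Boolean (n_proteins, 20) matrix of per-protein AAR presence.

    Equivalent to ``[aar_presence(s, min_len) for s in sequences]`` but
    computed in a single vectorized pass, which is what makes profiling
    simulated multi-megabyte proteomes cheap.
    """
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    n = len(sequences)
    out = np.zeros((n, N_AA), dtype=bool)
    if n == 0:
        return out
    codes, protein_idx = _concat_codes(sequences)
    L = codes.size
    if L < min_len:
        _validate_codes(codes)
        return out
    m = L - min_len + 1
    eq = np.ones(m, dtype=bool)
    head = codes[:m]
    for k in range(1, min_len):
        eq &= codes[k : k + m] == head
    hits = eq & (head != _SEP) & (head != _BREAK)
    _validate_codes(codes)
    if hits.any():
        pos = np.flatnonzero(hits)
        letters = _CODE_TO_INDEX[head[pos]]
        out[protein_idx[pos], letters] = True
    return out


def _validate_codes(codes: np.ndarray) -> None:
    bad = (_CODE_TO_INDEX[codes] < 0) & (codes != _SEP) & (codes != _BREAK)
    if bad.any():
        c = chr(int(codes[np.flatnonzero(bad)[0]]))
        raise ValueError(f"non-canonical character {c!r} in sequence input")


def substring_presence_matrix(
    sequences: Sequence[str], patterns: Sequence[str]
) -> np.ndarray:
    """Boolean (n_proteins, n_patterns) matrix of exact substring presence.

    Used for the random-tetrapeptide controls; the separator byte prevents
    matches spanning protein boundaries.
    """
    n = len(sequences)
    out = np.zeros((n, len(patterns)), dtype=bool)
    if n == 0 or not patterns:
        return out
    codes, protein_idx = _concat_codes(sequences)
    L = codes.size
    for j, pat in enumerate(patterns):
        p = encode(pat)
        k = p.size
        if k == 0 or L < k:
            continue
        m = L - k + 1
        eq = codes[:m] == p[0]
        for off in range(1, k):
            eq &= codes[off : off + m] == p[off]
        if eq.any():
            out[protein_idx[np.flatnonzero(eq)], j] = True
    return out


# ---------------------------------------------------------------------------
# Repeat profiles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RepeatProfile:
    """Per-proteome AAR presence profile.

    ``matrix`` is the (N, K) boolean presence matrix over ``symbols`` (the
    20 amino acids for homopolymer profiles; tetrapeptide controls reuse the
    same container with the anchor letters as symbols).  ``n[X]`` counts
    proteins containing >= 1 qualifying occurrence of X; ``n_pair[X, Z]``
    counts proteins containing both X and Z.
    """

    species_id: str
    protein_ids: tuple[str, ...]
    symbols: tuple[str, ...]
    matrix: np.ndarray
    min_len: int = DEFAULT_MIN_LEN

    def __post_init__(self) -> None:
        if self.matrix.shape != (len(self.protein_ids), len(self.symbols)):
            raise ValueError("presence matrix shape does not match ids/symbols")

    @property
    def N(self) -> int:
        """Number of proteins in the proteome."""
        return len(self.protein_ids)

    @property
    def n(self) -> pd.Series:
        """n_X: proteins containing X, indexed by symbol."""
        return pd.Series(self.matrix.sum(axis=0), index=list(self.symbols), name="n")

    @property
    def n_pair(self) -> pd.DataFrame:
        """Symmetric n_XZ: proteins containing both X and Z (diagonal = n_X)."""
        m = self.matrix.astype(np.int64)
        return pd.DataFrame(m.T @ m, index=list(self.symbols), columns=list(self.symbols))

    def presence_sets(self) -> dict[str, set[str]]:
        """protein_id -> set of symbols present."""
        syms = np.array(self.symbols)
        return {
            pid: set(syms[row])
            for pid, row in zip(self.protein_ids, self.matrix)
        }

    def bearing(self, symbol: str) -> set[str]:
        """Ids of proteins containing *symbol*."""
        j = self.symbols.index(symbol)
        return {pid for pid, flag in zip(self.protein_ids, self.matrix[:, j]) if flag}

    def to_tsv(self, path: str | Path) -> None:
        """Per-protein 0/1 presence matrix, one column per symbol."""
        df = pd.DataFrame(
            self.matrix.astype(int), index=list(self.protein_ids), columns=list(self.symbols)
        )
        df.to_csv(path, sep="\t", index_label="protein_id")

    @classmethod
    def from_tsv(
        cls, path: str | Path, species_id: str | None = None, min_len: int = DEFAULT_MIN_LEN
    ) -> "RepeatProfile":
        """Read a presence matrix written by :meth:`to_tsv`."""
        df = pd.read_csv(path, sep="\t", index_col="protein_id")
        return cls(
            species_id=species_id or Path(path).stem,
            protein_ids=tuple(str(i) for i in df.index),
            symbols=tuple(df.columns),
            matrix=df.to_numpy(dtype=bool),
            min_len=min_len,
        )


def profile_proteome(
    proteome: Proteome, min_len: int = DEFAULT_MIN_LEN
) -> RepeatProfile:
    """Build the AAR presence profile of a proteome."""
    if len(proteome) == 0:
        raise ValueError("cannot profile an empty proteome")
    mat = presence_matrix(_broken_sequences(proteome), min_len)
    return RepeatProfile(
        species_id=proteome.species_id,
        protein_ids=proteome.ids,
        symbols=AMINO_ACIDS,
        matrix=mat,
        min_len=min_len,
    )


def _broken_sequences(proteome: Proteome) -> list[str]:
    """Sequences with sanitization run breaks marked by tab characters."""
    if not proteome.breaks:
        return list(proteome.sequences)
    out = []
    for pid, seq in proteome.records:
        out.append("\t".join(proteome.segments(pid, seq)))
    return out


def aa_usage(proteome: Proteome) -> pd.Series:
    """Proteome-wide residue fractions over the 20 letters (sums to 1)."""
    if len(proteome) == 0:
        raise ValueError("cannot compute usage of an empty proteome")
    codes, _ = _concat_codes(proteome.sequences)
    keep = (codes != _SEP) & (codes != _BREAK)
    counts = np.bincount(_CODE_TO_INDEX[codes][keep], minlength=N_AA)
    total = counts.sum()
    return pd.Series(counts / total, index=list(AMINO_ACIDS), name="usage")


def usage_normalized_occurrence(pct: pd.Series, usage: pd.Series) -> pd.Series:
    """%X4 divided by the residue usage fraction f_X.

    Removes the trivial dependence of repeat occurrence on amino-acid
    content: a letter twice as common gets no credit for twice the runs.
    Letters with zero usage and zero occurrence map to 0; zero usage with
    nonzero occurrence is inconsistent input and raises.
    """
    pct = pct.reindex(list(AMINO_ACIDS))
    usage = usage.reindex(list(AMINO_ACIDS))
    bad = (usage == 0) & (pct > 0)
    if bad.any():
        raise ValueError(
            f"zero usage but nonzero occurrence for {list(pct.index[bad])}"
        )
    out = pd.Series(0.0, index=pct.index, name="pct_per_usage")
    ok = usage > 0
    out[ok] = pct[ok] / usage[ok]
    return out


def ortholog_presence_table(
    groups: Mapping[str, Mapping[str, Sequence[str]]],
    aar_set: Iterable[str] = AMINO_ACIDS,
    min_len: int = DEFAULT_MIN_LEN,
) -> pd.DataFrame:
    """Percent of each gene's orthologs, per taxon, containing each AAR.

    *groups* maps gene name -> taxon -> list of ortholog sequences (partial
    sequences included as-is).  Returns a tidy frame with columns
    ``gene, taxon, aar, pct, n_orthologs``; an empty ortholog list yields a
    missing (NaN) percentage rather than 0.
    """
    aar_list = [a for a in AMINO_ACIDS if a in set(aar_set)]
    rows = []
    for gene, by_taxon in groups.items():
        for taxon, seqs in by_taxon.items():
            if len(seqs) == 0:
                for aa in aar_list:
                    rows.append((gene, taxon, aa, np.nan, 0))
                continue
            mat = presence_matrix(list(seqs), min_len)
            for aa in aar_list:
                frac = mat[:, AA_INDEX[aa]].mean()
                rows.append((gene, taxon, aa, 100.0 * frac, len(seqs)))
    return pd.DataFrame(rows, columns=["gene", "taxon", "aar", "pct", "n_orthologs"])
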