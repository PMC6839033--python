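"""Random-tetrapeptide (RND4) control sets.

A control set is 20 non-homopolymeric tetrapeptides profiled by exact
substring matching with the identical downstream machinery as the X4
homopolymers, so that any phylogenetic or combinatorial signal specific to
homorepeats disappears under the control while composition effects remain.

Two schemes:

* ``reshuffle`` — the 80 residues of the 20 homopeptides (each letter x4)
  are randomly permuted and partitioned into 20 tetrapeptides, preserving
  the overall residue composition of the peptide set exactly.
* ``anchor_random`` — peptide i keeps letter i in first position and draws
  the remaining three residues i.i.d. uniformly, fully randomizing
  composition.

Any draw that produces a homopolymeric tetrapeptide is rejected and
redrawn: a control set must not contain the test pattern.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .alphabet import AMINO_ACIDS, N_AA
from .repeat_core import RepeatProfile, substring_presence_matrix
from .seqio import Proteome

_MAX_DRAWS = 10**6

#: Replicate labels: a–e for reshuffled sets, f–j for anchor-randomized.
RESHUFFLE_LABELS = ("a", "b", "c", "d", "e")
ANCHOR_LABELS = ("f", "g", "h", "i", "j")


@dataclass(frozen=True)
class TetrapeptideSet:
    label: str
    peptides: tuple[str, ...]
    scheme: str  # "reshuffle" | "anchor_random"
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.peptides) != N_AA:
            raise ValueError("a control set holds exactly 20 tetrapeptides")
        if any(len(p) != 4 for p in self.peptides):
            raise ValueError("all control peptides are tetrapeptides")
        if any(len(set(p)) == 1 for p in self.peptides):
            raise ValueError("control peptides must not be homopolymeric")


def _is_homopolymer(pep: Sequence[str]) -> bool:
    return len(set(pep)) == 1


def make_reshuffled_set(seed: int, label: str = "a") -> TetrapeptideSet:
    """Residue-level reshuffle of the 20 homopeptides.

    The 80-residue multiset (each letter exactly 4 times) is permuted and
    cut into 20 consecutive tetrapeptides; permutations yielding any
    homopolymeric peptide are rejected wholesale and redrawn.  Deterministic
    per seed.
    """
    rng = np.random.default_rng(seed)
    pool = np.repeat(np.array(list(AMINO_ACIDS)), 4)
    for _ in range(_MAX_DRAWS):
        perm = rng.permutation(pool)
        peps = ["".join(perm[i : i + 4]) for i in range(0, 80, 4)]
        if not any(_is_homopolymer(p) for p in peps):
            return TetrapeptideSet(label, tuple(peps), "reshuffle", seed)
    raise RuntimeError("rejection sampling did not terminate")  # pragma: no cover


def make_anchor_set(seed: int, label: str = "f") -> TetrapeptideSet:
    """Anchor-randomized set: peptide for letter X is X plus 3 uniform letters."""
    rng = np.random.default_rng(seed)
    peps: list[str] = []
    for aa in AMINO_ACIDS:
        for _ in range(_MAX_DRAWS):
            tail = "".join(rng.choice(list(AMINO_ACIDS), size=3))
            pep = aa + tail
            if not _is_homopolymer(pep):
                peps.append(pep)
                break
        else:  # pragma: no cover
            raise RuntimeError("rejection sampling did not terminate")
    return TetrapeptideSet(label, tuple(peps), "anchor_random", seed)


def make_replicate_sets(
    scheme: str, base_seed: int, n_replicates: int = 5
) -> list[TetrapeptideSet]:
    """Replicate control sets with independent derived seeds.

    Reshuffled replicates are labeled a–e, anchor-randomized f–j, matching
    the convention used for the published control analyses.
    """
    labels = RESHUFFLE_LABELS if scheme == "reshuffle" else ANCHOR_LABELS
    maker = make_reshuffled_set if scheme == "reshuffle" else make_anchor_set
    if scheme not in ("reshuffle", "anchor_random"):
        raise ValueError(f"unknown scheme {scheme!r}")
    children = np.random.SeedSequence(base_seed).spawn(n_replicates)
    return [
        maker(int(child.generate_state(1)[0] % 2**31), label=labels[i % len(labels)])
        for i, child in enumerate(children)
    ]


def profile_tetrapeptides(proteome: Proteome, tset: TetrapeptideSet) -> RepeatProfile:
    """Presence profile of the 20 control tetrapeptides in a proteome.

    Presence is exact contiguous substring match.  The result reuses
    :class:`RepeatProfile` with the canonical letters as symbols (symbol i
    stands for peptide i of the set), so %RND4, RR and OV flow through the
    identical parameter/clustering machinery with zero code branching.
    """
    if len(proteome) == 0:
        raise ValueError("cannot profile an empty proteome")
    from .repeat_core import _broken_sequences

    mat = substring_presence_matrix(_broken_sequences(proteome), tset.peptides)
    return RepeatProfile(
        species_id=proteome.species_id,
        protein_ids=proteome.ids,
        symbols=AMINO_ACIDS,
        matrix=mat,
        min_len=4,
    )


def write_tetrapeptide_sets(sets: Sequence[TetrapeptideSet], path: str | Path) -> None:
    """TSV export: label, scheme, seed, then the 20 peptides."""
    with open(path, "w", encoding="ascii") as fh:
        fh.write("label\tscheme\tseed\t" + "\t".join(AMINO_ACIDS) + "\n")
        for ts in sets:
            fh.write(
                f"{ts.label}\t{ts.scheme}\t{ts.seed}\t" + "\t".join(ts.peptides) + "\n"
            )
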