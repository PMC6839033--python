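"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the statistical structure the analysis assumes —
marginal per-AAR presence probabilities, pairwise co-occurrence boosts,
drift of those probabilities along a known phylogeny, AAR-assortative
interaction networks, and annotation tables with planted enrichment
factors — without attempting realistic protein evolution.  Every generator
is deterministic per seed and returns its ground truth alongside the data.

Background sequence is i.i.d. from a configurable residue composition
(default: database-average eukaryotic frequencies), so accidental
homopolymer runs occur at their natural rate (per protein roughly
(L-3)*f_X^4 for letter X); they are deliberately not suppressed, since the
scanner sees sequence, not intent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .alphabet import AA_INDEX, AMINO_ACIDS, N_AA
from .repeat_core import DEFAULT_MIN_LEN, RepeatProfile
from .seqio import Proteome, TreeTopology

#: Database-average amino-acid composition (fractions, alphabetical order).
DEFAULT_AA_FREQS: tuple[float, ...] = (
    0.0826, 0.0139, 0.0546, 0.0672, 0.0387, 0.0708, 0.0228, 0.0593,
    0.0581, 0.0966, 0.0241, 0.0406, 0.0474, 0.0394, 0.0553, 0.0660,
    0.0535, 0.0687, 0.0110, 0.0292,
)


def _norm_freqs(freqs: Sequence[float]) -> np.ndarray:
    f = np.asarray(freqs, dtype=float)
    if f.shape != (N_AA,) or (f < 0).any() or f.sum() <= 0:
        raise ValueError("aa_freqs must be 20 non-negative values")
    return f / f.sum()


@dataclass(frozen=True)
class ProteomeSpec:
    """Specification of one synthetic proteome.

    ``p_insert[X]`` is the probability that a protein receives at least one
    planted run of X; ``pair_boost[(X, Z)] = theta`` multiplies the joint
    presence probability of the pair to ``theta * p_X * p_Z`` (letters may
    appear in at most one boosted pair).  Planted run lengths are
    ``min_len + Poisson(run_length_excess)``.
    """

    n_proteins: int
    length_mean: float = 300.0
    length_sd: float = 100.0
    length_min: int = 60
    aa_freqs: tuple[float, ...] = DEFAULT_AA_FREQS
    p_insert: Mapping[str, float] = field(default_factory=dict)
    pair_boost: Mapping[tuple[str, str], float] = field(default_factory=dict)
    min_len: int = DEFAULT_MIN_LEN
    run_length_excess: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins <= 0:
            raise ValueError("n_proteins must be positive")
        for aa, p in self.p_insert.items():
            if aa not in AA_INDEX:
                raise ValueError(f"unknown amino acid {aa!r}")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"p_insert[{aa!r}]={p} outside [0, 1]")
        seen: set[str] = set()
        for (x, z), theta in self.pair_boost.items():
            if theta < 0:
                raise ValueError(f"pair_boost[{x},{z}] must be >= 0")
            if x in seen or z in seen or x == z:
                raise ValueError(
                    f"letter reused across boosted pairs at ({x},{z}); "
                    "boosted pairs must be letter-disjoint"
                )
            seen |= {x, z}
            px = self.p_insert.get(x, 0.0)
            pz = self.p_insert.get(z, 0.0)
            p11 = theta * px * pz
            if p11 > min(px, pz) + 1e-12 or 1 - px - pz + p11 < -1e-12:
                raise ValueError(
                    f"infeasible joint probability for pair ({x},{z}): "
                    f"theta={theta}, p_X={px}, p_Z={pz}"
                )
        _norm_freqs(self.aa_freqs)

    @property
    def p_vector(self) -> np.ndarray:
        return np.array([self.p_insert.get(aa, 0.0) for aa in AMINO_ACIDS])


def sample_presence(spec: ProteomeSpec, rng: np.random.Generator) -> np.ndarray:
    """Sample the planted-presence matrix (n_proteins, 20).

    Letters outside boosted pairs are independent Bernoulli(p_X).  Each
    boosted pair (X, Z) is drawn jointly with P(both) = theta*p_X*p_Z and
    the marginals preserved exactly, so the planted co-occurrence fold
    n_XZ*N/(n_X*n_Z) converges to theta.
    """
    n = spec.n_proteins
    p = spec.p_vector
    out = rng.random((n, N_AA)) < p[None, :]
    for (x, z), theta in spec.pair_boost.items():
        ix, iz = AA_INDEX[x], AA_INDEX[z]
        px, pz = p[ix], p[iz]
        p11 = theta * px * pz
        p10 = px - p11
        p01 = pz - p11
        p00 = 1.0 - p11 - p10 - p01
        cell_p = np.clip([p00, p01, p10, p11], 0.0, 1.0)
        cells = rng.choice(4, size=n, p=cell_p / cell_p.sum())
        out[:, ix] = cells >= 2          # 2=X only, 3=both
        out[:, iz] = (cells % 2) == 1    # 1=Z only, 3=both
    return out


def gen_proteome(spec: ProteomeSpec) -> tuple[Proteome, pd.DataFrame]:
    """Generate a proteome plus its planted-presence ground truth.

    Background residues are i.i.d. from ``aa_freqs``; for each selected
    letter one run (length ``min_len + Poisson``) is written at a uniform
    position, avoiding previously planted intervals where possible (20
    redraws, then overlap is accepted).  Detected presence can exceed the
    planted truth through accidental background runs — by design.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_proteins
    planted = sample_presence(spec, rng)
    width = len(str(n - 1))
    pids = tuple(f"{spec.seed}p{i:0{width}d}" for i in range(n))
    records = _realize_sequences(planted, spec, rng, pids)
    proteome = Proteome(species_id=f"synthetic_{spec.seed}", records=records)
    truth = pd.DataFrame(planted, index=list(pids), columns=list(AMINO_ACIDS))
    return proteome, truth


def _realize_sequences(
    planted: np.ndarray,
    spec: ProteomeSpec,
    rng: np.random.Generator,
    pids: Sequence[str],
) -> tuple[tuple[str, str], ...]:
    """Write background sequence and plant one run per selected letter."""
    n = planted.shape[0]
    freqs = _norm_freqs(spec.aa_freqs)
    lengths = np.maximum(
        np.round(rng.normal(spec.length_mean, spec.length_sd, size=n)).astype(int),
        spec.length_min,
    )
    letter_codes = np.frombuffer("".join(AMINO_ACIDS).encode("ascii"), dtype=np.uint8)
    total = int(lengths.sum())
    blob = letter_codes[rng.choice(N_AA, size=total, p=freqs)]
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    records: list[tuple[str, str]] = []
    for i in range(n):
        seq = blob[offsets[i]:offsets[i + 1]]
        sel = np.flatnonzero(planted[i])
        if sel.size:
            placed: list[tuple[int, int]] = []
            for j in sel:
                run_len = spec.min_len + int(rng.poisson(spec.run_length_excess))
                run_len = min(run_len, len(seq))
                start = 0
                for _attempt in range(20):
                    start = int(rng.integers(0, len(seq) - run_len + 1))
                    if all(start + run_len <= a or start >= b for a, b in placed):
                        break
                placed.append((start, start + run_len))
                seq[start:start + run_len] = letter_codes[j]
        records.append((pids[i], seq.tobytes().decode("ascii")))
    return tuple(records)


def gen_presence_profile(
    spec: ProteomeSpec, species_id: str | None = None
) -> RepeatProfile:
    """Presence-level profile drawn directly from the presence sampler.

    Skips sequence realization entirely: the returned profile contains the
    planted presence matrix itself.  Intended for screen-level calibration
    and power simulations where only the presence statistics matter; the
    sequence-level path is exercised by :func:`gen_proteome`.
    """
    rng = np.random.default_rng(spec.seed)
    mat = sample_presence(spec, rng)
    n = spec.n_proteins
    width = len(str(n - 1))
    return RepeatProfile(
        species_id=species_id or f"synthetic_{spec.seed}",
        protein_ids=tuple(f"{spec.seed}p{i:0{width}d}" for i in range(n)),
        symbols=AMINO_ACIDS,
        matrix=mat,
        min_len=spec.min_len,
    )


# ---------------------------------------------------------------------------
# Clade generation: parameter drift along a tree
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CladeSpec:
    """Root proteome spec + a time-scaled reference tree + drift scale.

    Parameters evolve root→leaves by a seeded Gaussian random walk with
    per-unit-branch-length standard deviation ``drift_scale``, applied to
    logit(p_X) for the 20 marginal presence probabilities and to the
    pairwise-association state z_XZ = atanh(rho_XZ) of a Gaussian copula
    over the presence indicators (a smooth monotone reparameterization of
    the log joint-odds of each pair; all 190 pairs drift, starting from
    neutrality at the root).  Leaves realize proteomes (or presence-level
    profiles) with exact marginals p_X and pairwise association rho_XZ.
    """

    newick: str
    root: ProteomeSpec
    drift_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.drift_scale < 0:
            raise ValueError("drift_scale must be >= 0")
        if self.root.pair_boost:
            raise ValueError(
                "CladeSpec drifts pairwise association itself; "
                "root.pair_boost must be empty"
            )


def _logit(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, 1e-9, 1 - 1e-9)
    return np.log(p / (1 - p))


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


_IU, _JU = np.triu_indices(N_AA, k=1)


def sample_presence_copula(
    p: np.ndarray, rho: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Presence matrix with exact marginals *p* and pairwise association.

    A latent Gaussian vector with correlation matrix built from the 190
    *rho* entries (projected to the PSD cone by eigenvalue clipping) is
    thresholded per letter at the p-quantile; thresholding preserves every
    marginal exactly whatever the correlation structure.
    """
    from scipy.special import ndtri

    C = np.eye(N_AA)
    C[_IU, _JU] = rho
    C[_JU, _IU] = rho
    w, V = np.linalg.eigh(C)
    A = V * np.sqrt(np.clip(w, 1e-9, None))
    G = rng.standard_normal((n, N_AA)) @ A.T
    G = G / np.sqrt((A**2).sum(axis=1))
    active = p > 0
    thresh = np.where(active, ndtri(np.clip(p, 1e-12, 1.0)), -np.inf)
    return G < thresh[None, :]


def gen_clade(
    cs: CladeSpec, sequences: bool = True
) -> tuple[dict[str, Proteome | RepeatProfile], dict[str, pd.DataFrame], TreeTopology]:
    """One proteome (or presence profile) per leaf, plus true leaf parameters.

    Returns ``(by_leaf, truth, topology)``; ``truth["p"]`` is the leaf x
    letter matrix of evolved presence probabilities and ``truth["rho"]``
    the leaf x pair matrix of copula correlations.  With
    ``sequences=False`` the leaves hold presence-level profiles instead of
    sequence proteomes.
    """
    import io as _io
    from skbio import TreeNode

    tree = TreeNode.read(_io.StringIO(cs.newick))
    leaves = [t.name for t in tree.tips()]
    if len(leaves) < 3:
        raise ValueError("clade tree needs at least 3 leaves")
    ss = np.random.SeedSequence(cs.seed)
    walk_ss, *leaf_seeds = ss.spawn(len(leaves) + 1)
    walk_rng = np.random.default_rng(walk_ss)

    # Drift only letters with a nonzero root probability.
    active = cs.root.p_vector > 0
    state: dict[int, tuple[np.ndarray, np.ndarray]] = {
        id(tree): (_logit(cs.root.p_vector), np.zeros(_IU.size))
    }
    leaf_p: dict[str, np.ndarray] = {}
    leaf_rho: dict[str, np.ndarray] = {}
    for node in tree.preorder(include_self=False):
        lp, z = state[id(node.parent)]
        bl = node.length if node.length is not None else 1.0
        sd = cs.drift_scale * np.sqrt(max(bl, 0.0))
        lp = lp + np.where(active, walk_rng.normal(0.0, sd, N_AA), 0.0)
        z = z + walk_rng.normal(0.0, sd, _IU.size)
        state[id(node)] = (lp, z)
        if node.is_tip():
            leaf_p[node.name] = np.where(active, _expit(lp), 0.0)
            leaf_rho[node.name] = np.tanh(z)

    by_leaf: dict[str, Proteome | RepeatProfile] = {}
    for leaf, child_ss in zip(leaves, leaf_seeds):
        child_seed = int(child_ss.generate_state(1)[0] % 2**31)
        rng = np.random.default_rng(child_seed)
        presence = sample_presence_copula(
            leaf_p[leaf], leaf_rho[leaf], cs.root.n_proteins, rng
        )
        width = len(str(cs.root.n_proteins - 1))
        pids = tuple(f"{leaf}_p{i:0{width}d}" for i in range(cs.root.n_proteins))
        if sequences:
            records = _realize_sequences(presence, cs.root, rng, pids)
            by_leaf[leaf] = Proteome(species_id=leaf, records=records)
        else:
            by_leaf[leaf] = RepeatProfile(
                species_id=leaf,
                protein_ids=pids,
                symbols=AMINO_ACIDS,
                matrix=presence,
                min_len=cs.root.min_len,
            )
    pair_names = [f"{AMINO_ACIDS[i]}+{AMINO_ACIDS[j]}" for i, j in zip(_IU, _JU)]
    truth = {
        "p": pd.DataFrame(
            {leaf: leaf_p[leaf] for leaf in leaves}, index=list(AMINO_ACIDS)
        ).T,
        "rho": pd.DataFrame(
            {leaf: leaf_rho[leaf] for leaf in leaves}, index=pair_names
        ).T,
    }
    return by_leaf, truth, TreeTopology.from_newick(cs.newick)


# ---------------------------------------------------------------------------
# Assortative interaction networks
# ---------------------------------------------------------------------------


def gen_network(
    presence: Mapping[str, set[str]],
    assortativity: Mapping[str, float],
    mean_degree: float,
    seed: int,
) -> "nx.Graph":
    """Random graph whose edges favor endpoints sharing an AAR.

    Edge probability is ``beta * prod_X alpha_X`` over the AARs X shared by
    both endpoints, with the baseline ``beta`` solved so the expected mean
    degree matches *mean_degree*.  Requires every alpha > 0; raises if the
    requested degree forces probabilities above 1.
    """
    import networkx as nx

    nodes = sorted(presence)
    n = len(nodes)
    if n < 2:
        raise ValueError("need at least 2 nodes")
    if any(a <= 0 for a in assortativity.values()):
        raise ValueError("assortativity factors must be > 0")
    rng = np.random.default_rng(seed)
    # per-node AAR indicator for the boosted AARs
    aars = sorted(assortativity)
    ind = np.array(
        [[aa in presence[v] for aa in aars] for v in nodes], dtype=bool
    )
    iu, ju = np.triu_indices(n, k=1)
    boost = np.ones(iu.size)
    for k, aa in enumerate(aars):
        shared = ind[iu, k] & ind[ju, k]
        boost[shared] *= assortativity[aa]
    target_edges = mean_degree * n / 2.0
    beta = target_edges / boost.sum()
    probs = beta * boost
    if (probs > 1).any():
        raise ValueError("infeasible mean degree: edge probability exceeds 1")
    keep = rng.random(iu.size) < probs
    g = nx.Graph()
    g.add_nodes_from(nodes)
    node_arr = np.array(nodes)
    g.add_edges_from(zip(node_arr[iu[keep]], node_arr[ju[keep]]))
    return g


# ---------------------------------------------------------------------------
# Annotation tables with planted enrichment
# ---------------------------------------------------------------------------


def gen_annotations(
    protein_ids: Sequence[str],
    term_sizes: Mapping[str, int],
    enrichment: Mapping[tuple[str, frozenset[str] | set[str]], float],
    seed: int,
    grouping: Mapping[str, tuple[str, str | None]] | None = None,
):
    """Annotation set with planted fold enrichments.

    *enrichment* maps ``(term, group_members)`` to a factor ``e``: inclusion
    probabilities are solved so the expected term size equals the target and
    the expected fold enrichment of the group equals ``e`` exactly
    (``p_in = e*S/N``; ``p_out`` absorbs the remainder).  ``e = 0`` yields
    zero overlap.  Infeasible combinations (p_in > 1 or p_out outside
    [0, 1]) raise.
    """
    from .seqio import AnnotationSet

    rng = np.random.default_rng(seed)
    ids = list(protein_ids)
    N = len(ids)
    id_index = {pid: i for i, pid in enumerate(ids)}
    by_term: dict[str, set[str]] = {}
    group_of_term: dict[str, np.ndarray] = {}
    e_of_term: dict[str, float] = {}
    for (term, members), e in enrichment.items():
        if e < 0:
            raise ValueError("enrichment factors must be >= 0")
        mask = np.zeros(N, dtype=bool)
        for pid in members:
            if pid in id_index:
                mask[id_index[pid]] = True
        group_of_term[term] = mask
        e_of_term[term] = e
    for term, size in term_sizes.items():
        if not 0 < size <= N:
            raise ValueError(f"term {term!r}: size {size} infeasible for N={N}")
        mask = group_of_term.get(term)
        e = e_of_term.get(term, 1.0)
        p = np.full(N, size / N)
        if mask is not None and mask.any() and e != 1.0:
            g = int(mask.sum())
            p_in = e * size / N
            p_out = (size - p_in * g) / (N - g) if N > g else 0.0
            if p_in > 1 + 1e-12 or p_out < -1e-12 or p_out > 1 + 1e-12:
                raise ValueError(
                    f"term {term!r}: infeasible enrichment e={e} "
                    f"(p_in={p_in:.3f}, p_out={p_out:.3f})"
                )
            p = np.where(mask, min(p_in, 1.0), np.clip(p_out, 0.0, 1.0))
        chosen = rng.random(N) < p
        by_term[term] = {ids[i] for i in np.flatnonzero(chosen)}
    return AnnotationSet(assignments=by_term, grouping=dict(grouping or {}))
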