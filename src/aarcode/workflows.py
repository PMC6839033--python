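"""End-to-end experiment drivers built from the library modules.

These functions wire the pipeline stages together for the simulation
studies the package uses to validate itself: null calibration and power of
the pairwise co-occurrence screen, recovery of planted functional
enrichments and network assortativity, and phylogeny recovery from AAR
parameter drift versus random-tetrapeptide controls.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .alphabet import AMINO_ACIDS, DP_AAR_SUBSET
from .enrichment_stats import (
    CombinationGroup,
    fold_enrichment,
    interactome_assortativity,
    pairwise_cooccurrence_screen,
    set_enrichment_screen,
)
from .null_models import make_reshuffled_set, profile_tetrapeptides
from .param_system import compute_parameters, parameter_table
from .profile_phylo import (
    adjust_table,
    average_linkage_cluster,
    dendrogram_to_unrooted,
    rf_distance,
    spearman_distance,
)
from .repeat_core import RepeatProfile, profile_proteome
from .seqio import TreeTopology
from .synthetic_data import (
    CladeSpec,
    ProteomeSpec,
    gen_annotations,
    gen_clade,
    gen_network,
    gen_presence_profile,
)

#: Default per-AAR presence probabilities for synthetic proteomes: moderate
#: for the eight DP-enriched letters, low background for the rest.
DEFAULT_P_INSERT: dict[str, float] = {
    **{aa: 0.02 for aa in AMINO_ACIDS},
    "A": 0.15, "E": 0.12, "G": 0.12, "H": 0.05,
    "P": 0.12, "Q": 0.10, "R": 0.06, "S": 0.15,
}

#: Uniform moderate presence probabilities used by the screen-calibration
#: studies and the clade experiment: every one of the 190 pairs is then
#: testable with valid chi-square expected counts (>= 5) at a few thousand
#: proteins.
UNIFORM_P_INSERT: dict[str, float] = {aa: 0.15 for aa in AMINO_ACIDS}

#: 9-leaf time-scaled (ultrametric) reference tree for the clade-recovery
#: experiment, labeled after the higher-order taxa of the cross-species
#: analyses.  Branch lengths are drift-time units: with every leaf at the
#: same total depth, the expected correlation between two leaf profiles is
#: a function of divergence time alone, which is the regime average-linkage
#: clustering reconstructs.
RECOVERY_TREE = (
    "((((pri:0.0075,rod:0.0075):0.015,(lau:0.0075,sau:0.0075):0.015):0.0275,"
    "((fis:0.0075,insa:0.0075):0.015,(insd:0.0075,nem:0.0075):0.015):0.0275):0.0,"
    "yea:0.05);"
)


def _spawn_seeds(base_seed: int, n: int) -> list[int]:
    return [
        int(s.generate_state(1)[0] % 2**31)
        for s in np.random.SeedSequence(base_seed).spawn(n)
    ]


# ---------------------------------------------------------------------------
# Screen calibration and power
# ---------------------------------------------------------------------------


def pairwise_screen_calibration(
    n_seeds: int = 200,
    n_proteins: int = 2000,
    p_insert: Mapping[str, float] | None = None,
    q: float = 0.05,
    base_seed: int = 0,
) -> pd.Series:
    """Type-I behavior of the 190-pair screen under independent placement.

    Returns the fraction of seeds with >= 1 (false) rejection — for
    independent tests under the complete null the BH family-wise rejection
    probability equals q — plus the mean per-pair rejection fraction.
    """
    p_insert = dict(p_insert or UNIFORM_P_INSERT)
    any_reject = 0
    frac_sum = 0.0
    raw_fracs = []
    for seed in _spawn_seeds(base_seed, n_seeds):
        spec = ProteomeSpec(n_proteins=n_proteins, p_insert=p_insert, seed=seed)
        profile = gen_presence_profile(spec)
        screen = pairwise_cooccurrence_screen(profile, q=q)
        if screen.n_rejected > 0:
            any_reject += 1
        frac_sum += screen.n_rejected / max(screen.n_tested, 1)
        raw_fracs.append(float((screen.results["p"] <= q).mean()))
    raw = np.asarray(raw_fracs)
    return pd.Series(
        dict(
            raw_type1_rate=raw.mean(),
            raw_type1_sem=raw.std(ddof=1) / np.sqrt(n_seeds),
            seed_rejection_rate=any_reject / n_seeds,
            mean_pair_rejection_fraction=frac_sum / n_seeds,
            n_seeds=n_seeds,
            n_proteins=n_proteins,
        )
    )


def pairwise_screen_power(
    theta: float = 5.0,
    pair: tuple[str, str] = ("A", "G"),
    n_seeds: int = 100,
    n_proteins: int = 5000,
    p_insert: Mapping[str, float] | None = None,
    q: float = 0.05,
    base_seed: int = 0,
) -> pd.Series:
    """Power to detect one planted pairwise association.

    A *theta*-fold joint-odds boost is planted for *pair*; power is the
    fraction of seeds in which that pair is BH-rejected with direction
    "over".
    """
    p_insert = dict(p_insert or UNIFORM_P_INSERT)
    x, z = pair
    unit = f"{min(x, z)}+{max(x, z)}"
    hits = 0
    for seed in _spawn_seeds(base_seed, n_seeds):
        spec = ProteomeSpec(
            n_proteins=n_proteins,
            p_insert=p_insert,
            pair_boost={(x, z): theta},
            seed=seed,
        )
        screen = pairwise_cooccurrence_screen(gen_presence_profile(spec), q=q)
        row = screen.results.loc[screen.results["unit_id"] == unit]
        if len(row) and bool(row["q_reject"].iloc[0]) and row["direction"].iloc[0] == "over":
            hits += 1
    return pd.Series(
        dict(power=hits / n_seeds, n_seeds=n_seeds, n_proteins=n_proteins, theta=theta)
    )


def enrichment_null_calibration(
    n_seeds: int = 200,
    n_proteins: int = 2000,
    n_terms: int = 20,
    term_size: int = 100,
    q: float = 0.05,
    base_seed: int = 0,
) -> pd.Series:
    """Set-enrichment screen under the null: terms drawn independently of
    AAR groups; reports the seed-level false-rejection rate."""
    any_reject = 0
    raw_fracs = []
    corrected_fracs = []
    for seed in _spawn_seeds(base_seed, n_seeds):
        spec = ProteomeSpec(n_proteins=n_proteins, p_insert=UNIFORM_P_INSERT, seed=seed)
        profile = gen_presence_profile(spec)
        ann = gen_annotations(
            profile.protein_ids,
            {f"t{i}": term_size for i in range(n_terms)},
            enrichment={},
            seed=seed + 1,
        )
        groups = [
            CombinationGroup(f"{aa}*", frozenset(profile.bearing(aa)))
            for aa in DP_AAR_SUBSET
        ]
        screen, _ = set_enrichment_screen(
            groups, ann.assignments, profile.protein_ids, q=q
        )
        if screen.n_rejected > 0:
            any_reject += 1
        raw_fracs.append(float((screen.results["p"] <= q).mean()))
        corrected_fracs.append(screen.n_rejected / max(screen.n_tested, 1))
    raw = np.asarray(raw_fracs)
    return pd.Series(
        dict(
            raw_type1_rate=raw.mean(),
            raw_type1_sem=raw.std(ddof=1) / np.sqrt(n_seeds),
            mean_rejection_fraction=float(np.mean(corrected_fracs)),
            seed_rejection_rate=any_reject / n_seeds,
            n_seeds=n_seeds,
        )
    )


def enrichment_recovery(
    e: float = 3.0,
    n_proteins: int = 10000,
    term_size: int = 500,
    aar: str = "A",
    seed: int = 0,
) -> pd.Series:
    """Plant a fold enrichment *e* of one term in the polyX group and
    measure the recovered fold and its BH decision."""
    spec = ProteomeSpec(n_proteins=n_proteins, p_insert=DEFAULT_P_INSERT, seed=seed)
    profile = gen_presence_profile(spec)
    group = frozenset(profile.bearing(aar))
    ann = gen_annotations(
        profile.protein_ids,
        {"t_planted": term_size, "t_null": term_size},
        enrichment={("t_planted", group): e},
        seed=seed + 1,
    )
    groups = [CombinationGroup(f"{aar}*", group)]
    screen, _ = set_enrichment_screen(groups, ann.assignments, profile.protein_ids)
    fold = fold_enrichment(group, ann.assignments["t_planted"], profile.protein_ids)
    planted_row = screen.results.loc[
        screen.results["unit_id"] == f"{aar}*|t_planted"
    ]
    return pd.Series(
        dict(
            fold=fold,
            rejected=bool(planted_row["q_reject"].iloc[0]) if len(planted_row) else False,
            n_proteins=n_proteins,
            e=e,
        )
    )


def assortativity_recovery(
    alpha: float = 3.0,
    n_nodes: int = 2000,
    aar: str = "A",
    p_bearing: float = 0.02,
    mean_degree: float = 6.0,
    n_focal: int = 20,
    n_seeds: int = 40,
    base_seed: int = 0,
) -> pd.Series:
    """Generate alpha-assortative networks and re-measure the normalized
    interactor proportion for the boosted AAR (mean over seeds).

    The generator's alpha multiplies the edge odds of same-AAR endpoint
    pairs; the set-based interactor-proportion estimator converges to alpha
    only when the bearing fraction is small and the focal set is a sparse
    sample of the bearers (otherwise finite-fraction and set-deduplication
    attenuation bias it downward) — hence the small ``p_bearing`` and the
    subsampled focal set, mirroring a small curated panel inside a large
    proteome.
    """
    estimates = []
    degrees = []
    for seed in _spawn_seeds(base_seed, n_seeds):
        rng = np.random.default_rng(seed)
        presence = {
            f"n{i:05d}": ({aar} if rng.random() < p_bearing else set())
            for i in range(n_nodes)
        }
        g = gen_network(presence, {aar: alpha}, mean_degree=mean_degree, seed=seed + 1)
        bearers = sorted(p for p, s in presence.items() if aar in s)
        focal = list(rng.choice(bearers, size=min(n_focal, len(bearers)),
                                replace=False))
        report = interactome_assortativity(g, presence, focal, [aar])
        row = report.per_aar.loc[report.per_aar["aar"] == aar].iloc[0]
        if np.isfinite(row["normalized_proportion"]):
            estimates.append(float(row["normalized_proportion"]))
        degrees.append(report.mean_degree)
    return pd.Series(
        dict(
            normalized_proportion=float(np.mean(estimates)),
            normalized_proportion_sem=float(
                np.std(estimates, ddof=1) / np.sqrt(len(estimates))
            ),
            mean_degree=float(np.mean(degrees)),
            alpha=alpha,
            n_nodes=n_nodes,
            n_seeds=n_seeds,
        )
    )


# ---------------------------------------------------------------------------
# Phylogeny recovery
# ---------------------------------------------------------------------------


def species_tree_from_profiles(
    profiles: Sequence[RepeatProfile],
    aar_subset: Iterable[str] | None = None,
    feature_block: str = "all",
) -> TreeTopology:
    """Parameter table -> adjusted features -> Spearman/average-linkage
    dendrogram -> unrooted topology, for >= 3 species profiles.

    ``feature_block`` selects which parameter families feed the clustering:
    ``"all"`` (RR + OV), ``"rr"`` or ``"ov"``.  The OV (co-occurrence)
    block carries the pairwise-association signal and is the default for
    the recovery experiment; restricting to a block mirrors the practice of
    excluding low-signal parameter families to limit clustering noise.
    """
    param_sets = [compute_parameters(p) for p in profiles]
    ft = parameter_table(param_sets, aar_subset)
    if feature_block == "rr":
        ft = ft.loc[[nm for nm in ft.index if nm.startswith("RR(")]]
    elif feature_block == "ov":
        ft = ft.loc[[nm for nm in ft.index if nm.startswith("OV(")]]
    elif feature_block != "all":
        raise ValueError(f"unknown feature_block {feature_block!r}")
    ft = adjust_table(ft)
    dist = spearman_distance(ft, axis="columns")
    dend = average_linkage_cluster(dist)
    return dendrogram_to_unrooted(dend)


def clade_recovery_experiment(
    n_seeds: int = 50,
    n_proteins: int = 3000,
    drift_scale: float = 1.5,
    newick: str = RECOVERY_TREE,
    p_insert: Mapping[str, float] | None = None,
    include_rnd4: bool = True,
    feature_block: str = "ov",
    sequences: bool = True,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Phylogeny recovery from drifting AAR parameters vs RND4 controls.

    Per seed: evolve presence probabilities and pairwise associations along
    the reference tree, realize sequence proteomes at the leaves, then
    recover the topology once from scanned AAR parameters and once from
    reshuffled-tetrapeptide (RND4) parameters computed on the *same*
    proteomes.  Reports the Robinson–Foulds distance of each recovered tree
    to the truth (a failed clustering — e.g. a feature table collapsing to
    constants — counts as a maximal-distance failure).
    """
    p_insert = dict(p_insert or UNIFORM_P_INSERT)
    truth = TreeTopology.from_newick(newick)
    max_rf = 2 * (len(truth.leaves) - 3)
    rows = []
    for seed in _spawn_seeds(base_seed, n_seeds):
        root = ProteomeSpec(n_proteins=n_proteins, p_insert=p_insert, seed=seed)
        cs = CladeSpec(newick=newick, root=root, drift_scale=drift_scale, seed=seed)
        by_leaf, _truth_params, _topo = gen_clade(cs, sequences=sequences)
        leaves = sorted(by_leaf)
        if sequences:
            profiles = [profile_proteome(by_leaf[lf]) for lf in leaves]
        else:
            profiles = [by_leaf[lf] for lf in leaves]
        rf_aar = _safe_rf(profiles, truth, max_rf, feature_block)
        rf_rnd = np.nan
        if include_rnd4 and sequences:
            tset = make_reshuffled_set(seed)
            rnd_profiles = [
                profile_tetrapeptides(by_leaf[lf], tset) for lf in leaves
            ]
            rf_rnd = _safe_rf(rnd_profiles, truth, max_rf, feature_block)
        rows.append(dict(seed=seed, rf_aar=rf_aar, rf_rnd4=rf_rnd))
    return pd.DataFrame(rows)


def _safe_rf(
    profiles: Sequence[RepeatProfile],
    truth: TreeTopology,
    max_rf: int,
    feature_block: str = "all",
) -> int:
    try:
        recovered = species_tree_from_profiles(profiles, feature_block=feature_block)
        return rf_distance(recovered, truth)
    except ValueError:
        return max_rf
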