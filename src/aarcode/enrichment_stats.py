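"""Contingency-table statistics for AAR co-occurrence and enrichment.

Everything here reduces to 2x2 tables: pairwise AAR co-occurrence within a
proteome, over-representation of AAR-bearing proteins in annotated
(functional) protein sets, interactome assortativity, and cross-species
fold-enrichment trends.  Multiple testing is controlled per screen family
with the Benjamini–Hochberg step-up procedure at FDR q (default 0.05);
screens are corrected independently of each other.

The Yates continuity correction is off by default and enabled only where a
screen explicitly asks for it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .alphabet import AMINO_ACIDS
from .repeat_core import RepeatProfile

logger = logging.getLogger(__name__)

DEFAULT_FDR_Q = 0.05


@dataclass(frozen=True)
class ContingencyResult:
    """One 2x2 evaluation: counts, chi2 statistic, p, fold, direction."""

    table: tuple[tuple[int, int], tuple[int, int]]
    statistic: float
    p: float
    fold: float
    direction: str  # "over" | "under"
    yates: bool
    min_expected: float  # smallest expected cell count (chi2 validity flag)


def _as_table(table) -> np.ndarray:
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (t < 0).any():
        raise ValueError("cell counts must be non-negative")
    return t


def _check_margins(t: np.ndarray) -> None:
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError(f"table has a zero margin and is untestable: {t.tolist()}")


def chi2_2x2(table, yates: bool = False) -> ContingencyResult:
    """Chi-squared test of independence on a 2x2 table.

    Without correction the statistic is N(ad-bc)^2/(r1 r2 c1 c2); with
    Yates, N(|ad-bc|-N/2)^2/(r1 r2 c1 c2) floored at 0.  p is two-sided
    from chi2 with 1 df.  The fold is observed/expected for the top-left
    (focal) cell.
    """
    t = _as_table(table)
    _check_margins(t)
    stat, p, _, expected = stats.chi2_contingency(t, correction=yates)
    exp00 = expected[0, 0]
    fold = t[0, 0] / exp00 if exp00 > 0 else 0.0
    return ContingencyResult(
        table=tuple(map(tuple, t.tolist())),
        statistic=float(stat),
        p=float(p),
        fold=float(fold),
        direction="over" if fold >= 1 else "under",
        yates=yates,
        min_expected=float(expected.min()),
    )


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p: total hypergeometric probability of tables
    (same margins) no more probable than the observed one."""
    t = _as_table(table)
    _check_margins(t)
    _, p = stats.fisher_exact(t, alternative="two-sided")
    return float(p)


def bh_fdr(pvals: Sequence[float], q: float = DEFAULT_FDR_Q) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up: (reject flags, adjusted p-values).

    Flags and adjusted values are returned in the original order.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


@dataclass
class EnrichmentScreen:
    """Outcome of one BH-corrected family of 2x2 tests."""

    results: pd.DataFrame  # unit_id, a,b,c,d, statistic, p, p_adj, fold, direction, q_reject
    fdr_q: float
    excluded: list[tuple[str, str]] = field(default_factory=list)  # (unit, reason)

    @property
    def n_tested(self) -> int:
        return len(self.results)

    @property
    def n_rejected(self) -> int:
        return int(self.results["q_reject"].sum())

    def rejected_units(self) -> list[str]:
        return list(self.results.loc[self.results["q_reject"], "unit_id"])

    def to_tsv(self, path) -> None:
        self.results.to_csv(path, sep="\t", index=False)


def _screen_from_tables(
    units: list[str],
    tables: list[np.ndarray],
    q: float,
    yates: bool,
    excluded: list[tuple[str, str]],
) -> EnrichmentScreen:
    rows = []
    for unit, t in zip(units, tables):
        res = chi2_2x2(t, yates=yates)
        rows.append(
            dict(
                unit_id=unit,
                a=t[0, 0], b=t[0, 1], c=t[1, 0], d=t[1, 1],
                statistic=res.statistic,
                p=res.p,
                fold=res.fold,
                direction=res.direction,
                min_expected=res.min_expected,
                low_expected=res.min_expected < 5,
            )
        )
    df = pd.DataFrame(
        rows,
        columns=["unit_id", "a", "b", "c", "d", "statistic", "p", "fold",
                 "direction", "min_expected", "low_expected"],
    )
    if len(df):
        reject, p_adj = bh_fdr(df["p"].to_numpy(), q)
        df["p_adj"] = p_adj
        df["q_reject"] = reject
    else:
        df["p_adj"] = []
        df["q_reject"] = []
    return EnrichmentScreen(results=df, fdr_q=q, excluded=excluded)


def pairwise_cooccurrence_screen(
    profile: RepeatProfile, q: float = DEFAULT_FDR_Q, yates: bool = False
) -> EnrichmentScreen:
    """Chi-squared screen of the 190 unordered AAR pairs of one proteome.

    For pair (X, Z) the table partitions the N proteins by X-bearing and
    Z-bearing status; BH correction runs across all testable pairs.  Pairs
    with a zero margin (e.g. an AAR absent from the proteome) are excluded
    and listed in ``screen.excluded``.
    """
    if profile.N <= 0:
        raise ValueError("profile must cover at least one protein")
    n = profile.n
    n_pair = profile.n_pair
    N = profile.N
    units: list[str] = []
    tables: list[np.ndarray] = []
    excluded: list[tuple[str, str]] = []
    for x, z in combinations(profile.symbols, 2):
        nx_, nz, nxz = int(n[x]), int(n[z]), int(n_pair.at[x, z])
        t = np.array(
            [[nxz, nx_ - nxz], [nz - nxz, N - nx_ - nz + nxz]], dtype=np.int64
        )
        unit = f"{x}+{z}"
        if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
            excluded.append((unit, "zero margin"))
            continue
        units.append(unit)
        tables.append(t)
    if excluded:
        logger.info(
            "pairwise screen: %d untestable pair(s) excluded", len(excluded)
        )
    return _screen_from_tables(units, tables, q, yates, excluded)


# ---------------------------------------------------------------------------
# Combination groups and set enrichment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CombinationGroup:
    """A protein set defined by AAR logic.

    ``spec`` is one of ``"X*"`` (all proteins bearing X), ``"X+Z"`` (bearing
    both) or ``"X-Z"`` (bearing X but not Z); ``X+Z`` and ``X-Z`` partition
    ``X*``.
    """

    spec: str
    members: frozenset[str]

    def __len__(self) -> int:
        return len(self.members)


def parse_group_spec(spec: str) -> tuple[str, str | None, str]:
    """Parse ``"X*"``, ``"X+Z"`` or ``"X-Z"`` -> (x, z, op)."""
    spec = spec.replace(" ", "")
    if len(spec) == 2 and spec[1] == "*":
        x, z, op = spec[0], None, "*"
    elif len(spec) == 3 and spec[1] in "+-":
        x, z, op = spec[0], spec[2], spec[1]
    else:
        raise ValueError(f"bad combination-group spec {spec!r}")
    for letter in (x,) + ((z,) if z else ()):
        if letter not in AMINO_ACIDS:
            raise ValueError(f"unknown amino-acid letter {letter!r} in {spec!r}")
    return x, z, op


def build_combination_group(profile: RepeatProfile, spec: str) -> CombinationGroup:
    """Materialize a combination group from a presence profile."""
    x, z, op = parse_group_spec(spec)
    has_x = profile.bearing(x)
    if op == "*":
        members = has_x
    else:
        has_z = profile.bearing(z)
        members = has_x & has_z if op == "+" else has_x - has_z
    return CombinationGroup(spec=spec.replace(" ", ""), members=frozenset(members))


def fold_enrichment(
    group: Iterable[str], annotated_set: Iterable[str], proteome_ids: Iterable[str]
) -> float:
    """(share of the annotated set within the group) / (its share overall).

    fold = (|group ∩ set| / |group|) / (|set| / N).
    """
    group = set(group)
    aset = set(annotated_set)
    universe = set(proteome_ids)
    if not group:
        raise ValueError("empty group")
    if not aset:
        raise ValueError("empty annotated set")
    n = len(universe)
    overlap = len(group & aset)
    return (overlap / len(group)) / (len(aset) / n)


def _enrichment_table(group: set[str], aset: set[str], universe: set[str]) -> np.ndarray:
    both = len(group & aset)
    return np.array(
        [
            [both, len(group) - both],
            [len(aset) - both, len(universe) - len(group) - len(aset) + both],
        ],
        dtype=np.int64,
    )


def set_enrichment_screen(
    groups: Sequence[CombinationGroup],
    annotated_sets: Mapping[str, Iterable[str]],
    proteome_ids: Iterable[str],
    q: float = DEFAULT_FDR_Q,
    yates: bool = False,
) -> tuple[EnrichmentScreen, pd.DataFrame]:
    """Screen every (combination group, annotated set) association.

    Each association is a 2x2 split of the proteome by group membership and
    set membership; BH runs across all screened associations.  Returns the
    screen plus a (group x set) matrix of chi2 statistics for heat-map
    clustering; empty groups/sets or zero-margin tables are skipped and
    flagged.
    """
    universe = set(proteome_ids)
    units: list[str] = []
    tables: list[np.ndarray] = []
    excluded: list[tuple[str, str]] = []
    chi2_matrix = pd.DataFrame(
        np.nan, index=[g.spec for g in groups], columns=list(annotated_sets)
    )
    for g in groups:
        gset = set(g.members) & universe
        for name, members in annotated_sets.items():
            aset = set(members) & universe
            unit = f"{g.spec}|{name}"
            if not gset or not aset:
                excluded.append((unit, "empty group or set"))
                continue
            t = _enrichment_table(gset, aset, universe)
            if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
                excluded.append((unit, "zero margin"))
                continue
            units.append(unit)
            tables.append(t)
    screen = _screen_from_tables(units, tables, q, yates, excluded)
    for unit, stat in zip(screen.results["unit_id"], screen.results["statistic"]):
        gspec, name = unit.split("|", 1)
        chi2_matrix.at[gspec, name] = stat
    return screen, chi2_matrix


def normalized_chi2_matrix(chi2_matrix: pd.DataFrame) -> pd.DataFrame:
    """Column-wise mean-centered, max-normalized chi2 matrix (heat-map
    export); the raw matrix is the other supported export."""
    m = chi2_matrix.copy()
    denom = m.abs().max(axis=0).replace(0, np.nan)
    m = m / denom
    return m - m.mean(axis=0)


def cross_species_trend(
    per_species: Sequence[tuple[RepeatProfile, Mapping[str, Iterable[str]]]],
    group_spec: str,
    term_name: str,
    normalize_to: str | None = None,
    yates: bool = False,
) -> pd.DataFrame:
    """Fold enrichment (and chi2 p) of one term in one AAR group, per species.

    *per_species* is an ordered list of (profile, named annotated sets);
    missing terms or empty groups yield NaN cells flagged in ``missing``.
    With *normalize_to*, the fold series is divided by that species' fold.
    """
    if len(per_species) < 2:
        raise ValueError("a trend needs at least two species")
    rows = []
    for profile, sets in per_species:
        sp = profile.species_id
        ids = set(profile.protein_ids)
        try:
            group = build_combination_group(profile, group_spec)
            aset = set(sets[term_name]) & ids if term_name in sets else set()
            if not group.members or not aset:
                raise KeyError("empty group or missing term")
            fold = fold_enrichment(group.members, aset, ids)
            res = chi2_2x2(_enrichment_table(set(group.members), aset, ids), yates)
            rows.append(dict(species_id=sp, fold=fold, statistic=res.statistic,
                             p=res.p, missing=False))
        except (KeyError, ValueError):
            rows.append(dict(species_id=sp, fold=np.nan, statistic=np.nan,
                             p=np.nan, missing=True))
    df = pd.DataFrame(rows)
    if normalize_to is not None:
        base = df.loc[df["species_id"] == normalize_to, "fold"]
        if base.empty or not np.isfinite(base.iloc[0]) or base.iloc[0] == 0:
            raise ValueError(f"cannot normalize to species {normalize_to!r}")
        df["fold_normalized"] = df["fold"] / base.iloc[0]
    return df


# ---------------------------------------------------------------------------
# Interactome assortativity
# ---------------------------------------------------------------------------


@dataclass
class AssortativityReport:
    """Per-AAR interactor enrichment, edge-level sharing, and focal degrees."""

    per_aar: pd.DataFrame    # aar, n_interactors, frac_bearing, proteome_frac,
                             # normalized_proportion, statistic, p
    edge_level: pd.Series    # n_edges, frac_both_bearing, expected_frac, statistic, p
    mean_degree: float
    sem_degree: float
    n_focal_used: int
    n_focal_missing: int


def interactome_assortativity(
    network: nx.Graph,
    presence: Mapping[str, set[str]],
    focal_set: Iterable[str],
    aar_set: Iterable[str],
) -> AssortativityReport:
    """Do the partners of AAR-bearing focal proteins bear the same AARs?

    For each AAR X: among the distinct interactors of focal proteins bearing
    X, the fraction bearing X, normalized to the proteome-wide X-bearing
    fraction (values > 1 mean assortative excess), with a chi2 test of the
    interactor count against that proteome-wide expectation.  Edge-level:
    the fraction of focal-incident edges whose two endpoints both bear some
    AAR in *aar_set*, against the independence expectation (squared marginal
    bearing fraction).  Also reports the focal set's mean degree (± SEM).

    ``presence`` maps protein id -> set of AAR letters; proteins absent from
    it are treated as bearing nothing.  Focal proteins absent from the
    network are excluded with a logged count.
    """
    aars = [a for a in AMINO_ACIDS if a in set(aar_set)]
    focal = sorted(set(focal_set))
    in_net = [p for p in focal if p in network]
    n_missing = len(focal) - len(in_net)
    if n_missing:
        logger.info("%d focal protein(s) absent from the network", n_missing)
    if not in_net:
        raise ValueError("no focal protein is present in the network")

    proteome = list(presence)
    n_prot = len(proteome)

    def bears(p: str, aa: str) -> bool:
        return aa in presence.get(p, ())

    rows = []
    for aa in aars:
        base_frac = sum(1 for p in proteome if bears(p, aa)) / n_prot
        bearers = [p for p in in_net if bears(p, aa)]
        interactors = set()
        for p in bearers:
            interactors |= set(network.neighbors(p))
        k = len(interactors)
        if k == 0:
            rows.append(dict(aar=aa, n_interactors=0, frac_bearing=np.nan,
                             proteome_frac=base_frac, normalized_proportion=np.nan,
                             statistic=np.nan, p=np.nan))
            continue
        hit = sum(1 for p in interactors if bears(p, aa))
        frac = hit / k
        norm = frac / base_frac if base_frac > 0 else np.nan
        # chi2 goodness of fit of interactor bearing counts against the
        # proteome-wide expectation (1 df)
        if 0 < base_frac < 1:
            gof = stats.chisquare(
                [hit, k - hit], f_exp=[base_frac * k, (1 - base_frac) * k]
            )
            stat, p = float(gof.statistic), float(gof.pvalue)
        else:
            stat, p = np.nan, np.nan
        rows.append(dict(aar=aa, n_interactors=k, frac_bearing=frac,
                         proteome_frac=base_frac, normalized_proportion=norm,
                         statistic=stat, p=p))
    per_aar = pd.DataFrame(rows)

    # Edge level: focal-incident edges with both endpoints bearing any AAR.
    def bears_any(p: str) -> bool:
        s = presence.get(p, set())
        return any(a in s for a in aars)

    edges = [(u, v) for u in in_net for v in network.neighbors(u)]
    seen = set()
    uniq = []
    for u, v in edges:
        key = (u, v) if u <= v else (v, u)
        if key not in seen:
            seen.add(key)
            uniq.append(key)
    n_edges = len(uniq)
    both = sum(1 for u, v in uniq if bears_any(u) and bears_any(v))
    marginal = sum(1 for p in proteome if bears_any(p)) / n_prot
    expected_frac = marginal**2
    if n_edges and 0 < expected_frac < 1:
        gof = stats.chisquare(
            [both, n_edges - both],
            f_exp=[expected_frac * n_edges, (1 - expected_frac) * n_edges],
        )
        stat, p = float(gof.statistic), float(gof.pvalue)
    else:
        stat, p = np.nan, np.nan
    edge_level = pd.Series(
        dict(n_edges=n_edges,
             frac_both_bearing=both / n_edges if n_edges else np.nan,
             expected_frac=expected_frac, statistic=stat, p=p)
    )

    degrees = np.array([network.degree(p) for p in in_net], dtype=float)
    mean_deg = float(degrees.mean())
    sem_deg = float(degrees.std(ddof=1) / np.sqrt(len(degrees))) if len(degrees) > 1 else 0.0
    return AssortativityReport(
        per_aar=per_aar,
        edge_level=edge_level,
        mean_degree=mean_deg,
        sem_degree=sem_deg,
        n_focal_used=len(in_net),
        n_focal_missing=n_missing,
    )
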