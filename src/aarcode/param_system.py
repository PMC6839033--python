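"""The AAR parameter system: %X4 vectors, RR and OV matrices, taxon means.

For one proteome of N proteins, with n_X proteins containing an AAR of
amino acid X and n_XZ containing AARs of both X and Z:

    %X4        = 100 * n_X / N
    %(X4+Z4)   = 100 * n_XZ / N
    RR(X4/Z4)  = %X4 / %Z4            (relative occurrence of two AARs)
    OV(X4+Z4)  = %(X4+Z4) / (%X4)^2   (co-occurrence of Z among X bearers,
                                       normalized to the size of the X group)

Any ratio whose denominator is 0 is assigned exactly 0.  On the diagonals,
RR(X/X) = 1 and OV(X+X) = 1/%X4 wherever %X4 > 0.  All percentages are on
the 0–100 scale package-wide (:data:`PERCENT_SCALE`); OV magnitudes depend
on this convention, so it is asserted in tests and must not be changed
locally.  The 20x20 matrices give 400 RR + 400 OV = 800 parameters per
proteome, or 2*k^2 when restricted to a k-letter subset (k=8 -> 128).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .repeat_core import RepeatProfile

#: Single global scale constant for all percentage-valued quantities.
PERCENT_SCALE = 100.0


@dataclass(frozen=True)
class ParameterSet:
    """%X4 vector plus pairwise co-occurrence, RR and OV matrices."""

    species_id: str
    pct: pd.Series          # %X4, length 20 (or k for control profiles)
    pct_pair: pd.DataFrame  # %(X4+Z4), symmetric, diagonal = %X4
    rr: pd.DataFrame        # RR(X4/Z4) = pct[X]/pct[Z], zero rule applied
    ov: pd.DataFrame        # OV(X4+Z4) = pct_pair[X,Z]/pct[X]^2, zero rule

    @property
    def symbols(self) -> tuple[str, ...]:
        return tuple(self.pct.index)

    def to_json_dict(self) -> dict:
        return {
            "species_id": self.species_id,
            "symbols": list(self.symbols),
            "pct": self.pct.tolist(),
            "pct_pair": self.pct_pair.to_numpy().tolist(),
            "rr": self.rr.to_numpy().tolist(),
            "ov": self.ov.to_numpy().tolist(),
        }


def compute_parameters(profile: RepeatProfile) -> ParameterSet:
    """Compute the full parameter set of one repeat profile."""
    if profile.N <= 0:
        raise ValueError("profile must cover at least one protein")
    symbols = list(profile.symbols)
    pct = PERCENT_SCALE * profile.n / profile.N
    pct.name = "pct"
    pct_pair = PERCENT_SCALE * profile.n_pair / profile.N

    p = pct.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        rr = np.where(p[None, :] > 0, p[:, None] / p[None, :], 0.0)
        ov = np.where(
            (p[:, None] > 0), pct_pair.to_numpy() / np.square(p)[:, None], 0.0
        )
    return ParameterSet(
        species_id=profile.species_id,
        pct=pct,
        pct_pair=pct_pair,
        rr=pd.DataFrame(rr, index=symbols, columns=symbols),
        ov=pd.DataFrame(ov, index=symbols, columns=symbols),
    )


def feature_vector(
    ps: ParameterSet, aar_subset: Iterable[str] | None = None
) -> pd.Series:
    """Flatten a ParameterSet into a named parameter vector.

    Full mode: 400 RR entries then 400 OV entries, row-major in the fixed
    alphabetical letter order, names ``RR(X/Z)`` and ``OV(X+Z)``.  Subset
    mode with k letters keeps the ordered pairs within the subset (2*k^2
    entries; the 8-letter developmental subset gives 128).  Diagonal RR
    entries (all 1) are retained: they carry no signal and are dropped later
    as constant rows by the clustering preprocessing, not here.
    """
    if aar_subset is None:
        letters = list(ps.symbols)
    else:
        subset = set(aar_subset)
        letters = [a for a in ps.symbols if a in subset]
        if not letters:
            raise ValueError("aar_subset is empty or disjoint from the symbols")
        unknown = subset - set(ps.symbols)
        if unknown:
            raise ValueError(f"unknown letters in aar_subset: {sorted(unknown)}")
    names: list[str] = []
    values: list[float] = []
    for x in letters:
        for z in letters:
            names.append(f"RR({x}/{z})")
            values.append(float(ps.rr.at[x, z]))
    for x in letters:
        for z in letters:
            names.append(f"OV({x}+{z})")
            values.append(float(ps.ov.at[x, z]))
    return pd.Series(values, index=names, name=ps.species_id)


def parameter_table(
    param_sets: Sequence[ParameterSet], aar_subset: Iterable[str] | None = None
) -> pd.DataFrame:
    """Feature table with parameters as rows ("genes") and species as
    columns ("arrays"), ready for the clustering pipeline."""
    cols = [feature_vector(ps, aar_subset) for ps in param_sets]
    return pd.concat(cols, axis=1)


def pct_table(param_sets: Sequence[ParameterSet]) -> pd.DataFrame:
    """%X4 table, letters x species."""
    return pd.concat(
        [ps.pct.rename(ps.species_id) for ps in param_sets], axis=1
    )


@dataclass(frozen=True)
class TaxonSummary:
    """Element-wise means (and SEMs) of member-species parameter sets."""

    taxon_id: str
    member_species: tuple[str, ...]
    m_pct: pd.Series
    m_rr: pd.DataFrame
    m_ov: pd.DataFrame
    sem_pct: pd.Series
    sem_rr: pd.DataFrame
    sem_ov: pd.DataFrame
    single_member: bool

    @property
    def n_members(self) -> int:
        return len(self.member_species)


def _mean_sem(arrays: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray, bool]:
    stack = np.stack(arrays)
    mean = stack.mean(axis=0)
    k = stack.shape[0]
    if k == 1:
        # SEM undefined for a single member; reported as 0 with a flag.
        return mean, np.zeros_like(mean), True
    sem = stack.std(axis=0, ddof=1) / np.sqrt(k)
    return mean, sem, False


def taxon_means(
    param_sets: Sequence[ParameterSet], taxon_map: Mapping[str, str]
) -> list[TaxonSummary]:
    """Per-taxon element-wise arithmetic means (m%X4, mRR, mOV) with SEMs.

    Only species present in *taxon_map* contribute; every mapped species
    must be among *param_sets* and every taxon must have >= 1 member.
    """
    by_species = {ps.species_id: ps for ps in param_sets}
    missing = sorted(set(taxon_map) - set(by_species))
    if missing:
        raise ValueError(f"taxon_map species without parameter sets: {missing}")
    taxa: dict[str, list[str]] = {}
    for sp, taxon in taxon_map.items():
        taxa.setdefault(taxon, []).append(sp)
    out: list[TaxonSummary] = []
    for taxon in sorted(taxa):
        members = sorted(taxa[taxon])
        sets = [by_species[sp] for sp in members]
        symbols = list(sets[0].symbols)
        m_pct, s_pct, single = _mean_sem([ps.pct.to_numpy(float) for ps in sets])
        m_rr, s_rr, _ = _mean_sem([ps.rr.to_numpy(float) for ps in sets])
        m_ov, s_ov, _ = _mean_sem([ps.ov.to_numpy(float) for ps in sets])
        out.append(
            TaxonSummary(
                taxon_id=taxon,
                member_species=tuple(members),
                m_pct=pd.Series(m_pct, index=symbols, name=taxon),
                m_rr=pd.DataFrame(m_rr, index=symbols, columns=symbols),
                m_ov=pd.DataFrame(m_ov, index=symbols, columns=symbols),
                sem_pct=pd.Series(s_pct, index=symbols, name=taxon),
                sem_rr=pd.DataFrame(s_rr, index=symbols, columns=symbols),
                sem_ov=pd.DataFrame(s_ov, index=symbols, columns=symbols),
                single_member=single,
            )
        )
    return out


def taxon_parameter_table(
    summaries: Sequence[TaxonSummary], aar_subset: Iterable[str] | None = None
) -> pd.DataFrame:
    """mRR/mOV feature table, parameters x taxa (analogue of
    :func:`parameter_table` at the taxon level)."""
    cols = []
    for ts in summaries:
        ps = ParameterSet(
            species_id=ts.taxon_id,
            pct=ts.m_pct,
            pct_pair=ts.m_ov * 0,  # unused by feature_vector
            rr=ts.m_rr,
            ov=ts.m_ov,
        )
        cols.append(feature_vector(ps, aar_subset))
    return pd.concat(cols, axis=1)


def taxon_pct_table(summaries: Sequence[TaxonSummary]) -> pd.DataFrame:
    """m%X4 table, taxa as rows and letters as columns (PCA orientation)."""
    return pd.DataFrame(
        {ts.taxon_id: ts.m_pct for ts in summaries}
    ).T
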