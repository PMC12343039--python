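"""Ballast accounting: per-lorica mass estimates, summaries, derived metrics.

The central quantity is the per-lorica biomineral ballast

    B = Σ_i n_i · w_i  +  Σ_j V_j · c        [pg]

where ``n_i`` are lith counts of coccolith taxon *i* with per-lith CaCO3
mass ``w_i`` (pg), ``V_j`` are diatom-particle biovolumes (μm³) and
``c = 0.014 pg Si/μm³`` is the biovolume→silica conversion. Direct ``mass_pg``
observations enter verbatim. Downstream the module provides:

* assemblage summaries (per-taxon mean ± *population* sd over all loricae in
  a group, absent taxa counting as zero, and "x of n" occurrence counts) —
  the layout of published per-lorica survey tables;
* lorica-type classification (diatom-type / heavy-coccolith-dominated /
  other) with configurable dominance threshold;
* the extra-weight fraction of ballast relative to the ~40 000 ± 20 000 pg
  dry weight of a bare lorica;
* ratios of group mean ballast between regions (cold vs warm water
  populations);
* a tintinnid × particle preference matrix ordered by lorica oral diameter
  (rows) and lith size (columns).

Population sd (divisor *n*) is deliberate: published summaries of this data
type follow that convention, and the packaged fixtures only reproduce under
it (n−1 gives visibly different values).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .ledger import LoricaRecord, ParticleObservation, StudyDataset
from .reference import (
    ConversionConstants,
    ParticleMassReference,
    fragment_silica_mass,
    logger,
)


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (report display rule)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def population_sd(values: Sequence[float]) -> float:
    """Standard deviation with divisor n (population convention)."""
    return float(np.std(np.asarray(values, dtype=float), ddof=0))


# ---------------------------------------------------------------------------
# Per-lorica ballast

@dataclass(frozen=True)
class BallastEstimate:
    lorica_id: str
    caco3_by_taxon: dict[str, float]
    silica_by_taxon: dict[str, float]

    @property
    def caco3_total(self) -> float:
        return sum(self.caco3_by_taxon.values())

    @property
    def silica_total(self) -> float:
        return sum(self.silica_by_taxon.values())

    @property
    def total(self) -> float:
        return self.caco3_total + self.silica_total

    @property
    def mass_by_taxon(self) -> dict[str, float]:
        out = dict(self.caco3_by_taxon)
        for taxon, pg in self.silica_by_taxon.items():
            out[taxon] = out.get(taxon, 0.0) + pg
        return out

    @property
    def percent_by_taxon(self) -> Optional[dict[str, float]]:
        return percent_composition(self)


def estimate_lorica_ballast(
    lorica: LoricaRecord,
    observations: Iterable[ParticleObservation],
    reference: ParticleMassReference,
) -> BallastEstimate:
    """Accumulate CaCO3 and silica masses for one lorica.

    Coccolith ``count`` entries contribute count × per-lith mass (aliases
    resolved); ``mass_pg`` entries contribute verbatim; diatom
    ``biovolume_um3`` entries are converted to silica; diatom ``count``
    entries use the reference biovolume per particle.
    """
    caco3: dict[str, float] = {}
    silica: dict[str, float] = {}
    seen_types: dict[tuple[str, str], set[str]] = {}
    for obs in observations:
        if obs.lorica_id != lorica.lorica_id:
            raise ValueError(
                f"observation for {obs.lorica_id!r} passed with lorica {lorica.lorica_id!r}"
            )
        key = (obs.particle_taxon, obs.particle_kind)
        seen_types.setdefault(key, set()).add(obs.quantity_type)
        if obs.particle_kind == "coccolith":
            if obs.quantity_type == "count":
                pg = obs.quantity * reference.resolve_coccolith(obs.particle_taxon).lith_mass
            else:  # mass_pg
                pg = obs.quantity
            caco3[obs.particle_taxon] = caco3.get(obs.particle_taxon, 0.0) + pg
        else:
            if obs.quantity_type == "mass_pg":
                pg = obs.quantity
            elif obs.quantity_type == "biovolume_um3":
                pg = fragment_silica_mass(obs.quantity, reference.constants)
            else:  # count of a reference particle class
                kind = "whole_cell" if obs.particle_kind == "diatom_cell" else "fragment"
                spec = reference.resolve_diatom(obs.particle_taxon, kind)
                pg = fragment_silica_mass(obs.quantity * spec.biovolume, reference.constants)
            silica[obs.particle_taxon] = silica.get(obs.particle_taxon, 0.0) + pg
    for key, types in seen_types.items():
        if len(types) > 1:
            logger.info("lorica %s: %s/%s observed with mixed quantity types %s",
                        lorica.lorica_id, key[0], key[1], sorted(types))
    return BallastEstimate(lorica_id=lorica.lorica_id,
                           caco3_by_taxon=caco3, silica_by_taxon=silica)


def percent_composition(estimate: BallastEstimate,
                        rounded: bool = False) -> Optional[dict[str, float]]:
    """Per-taxon share of total ballast in percent.

    Returns ``None`` for a zero-total lorica (composition undefined).
    With ``rounded=True`` percents are integer, half away from zero.
    """
    total = estimate.total
    if total <= 0:
        return None
    pct = {t: 100.0 * pg / total for t, pg in estimate.mass_by_taxon.items()}
    if rounded:
        return {t: float(round_half_away(p)) for t, p in pct.items()}
    return pct


def estimate_dataset(dataset: StudyDataset) -> dict[str, BallastEstimate]:
    """Ballast estimates for every lorica in a dataset, keyed by lorica_id."""
    by_lorica: dict[str, list[ParticleObservation]] = {
        lor.lorica_id: [] for lor in dataset.loricae
    }
    for obs in dataset.observations:
        by_lorica[obs.lorica_id].append(obs)
    return {
        lor.lorica_id: estimate_lorica_ballast(lor, by_lorica[lor.lorica_id], dataset.reference)
        for lor in dataset.loricae
    }


# ---------------------------------------------------------------------------
# Lorica-type classification

@dataclass(frozen=True)
class ClassificationPolicy:
    """Rules for labelling a lorica by its dominant ballast component."""

    heavy_taxa: frozenset[str] = frozenset({"Calcidiscus", "Coccolithus"})
    dominance_threshold: float = 0.5
    diatom_cell_overrides: bool = True


@dataclass(frozen=True)
class LoricaTypeLabel:
    label: str
    dominant_share: float


def classify_lorica(
    estimate: BallastEstimate,
    observations: Iterable[ParticleObservation],
    policy: ClassificationPolicy | None = None,
    reference: ParticleMassReference | None = None,
) -> LoricaTypeLabel:
    """Label a lorica: diatom-type, <heavy taxon>-dominated, or other.

    Priority: (1) any whole diatom cell present → ``diatom-type``; (2) a
    heavy coccolith taxon holding a mass share ≥ the dominance threshold →
    ``<taxon>-dominated``; (3) ``other``. Dominance ties go to the larger
    share, then the heavier per-lith mass, then lexicographic order.
    """
    if policy is None:
        policy = ClassificationPolicy()
    obs_list = list(observations)
    shares = percent_composition(estimate) or {}
    dominant_share = max(shares.values()) / 100.0 if shares else 0.0

    if policy.diatom_cell_overrides and any(
        o.particle_kind == "diatom_cell" and o.quantity > 0 for o in obs_list
    ):
        return LoricaTypeLabel(label="diatom-type", dominant_share=dominant_share)

    candidates = [
        (shares.get(t, 0.0) / 100.0, t) for t in policy.heavy_taxa
        if shares.get(t, 0.0) / 100.0 >= policy.dominance_threshold
    ]
    if candidates:
        def _lith_mass(taxon: str) -> float:
            if reference is not None and reference.knows_coccolith(taxon):
                return reference.resolve_coccolith(taxon).lith_mass
            return 0.0

        candidates.sort(key=lambda st: (-st[0], -_lith_mass(st[1]), st[1]))
        if len(candidates) > 1 and candidates[0][0] == candidates[1][0]:
            logger.info("dominance tie between %s; broken by lith mass then name",
                        [t for _, t in candidates])
        share, taxon = candidates[0]
        return LoricaTypeLabel(label=f"{taxon}-dominated", dominant_share=share)
    return LoricaTypeLabel(label="other", dominant_share=dominant_share)


# ---------------------------------------------------------------------------
# Assemblage summaries

@dataclass(frozen=True)
class AssemblageSummary:
    """Group-level twin of a published per-lorica survey table footer."""

    key: tuple[str, ...]
    n: int
    per_taxon_mean: dict[str, float]
    per_taxon_sd: dict[str, float]
    occurrence: dict[str, tuple[int, int]]
    total_mean: float
    total_sd: float
    percent_mean: dict[str, float] = field(default_factory=dict)
    percent_sd: dict[str, float] = field(default_factory=dict)

    def occurrence_str(self, taxon: str) -> str:
        x, n = self.occurrence.get(taxon, (0, self.n))
        return f"{x} of {n}"


def summarize_assemblage(
    dataset: StudyDataset,
    group_by: Sequence[str] = ("tintinnid_taxon", "locality"),
) -> list[AssemblageSummary]:
    """Per-group per-taxon mean ± population sd, occurrence, and totals.

    ``group_by`` names lorica metadata fields (``tintinnid_taxon``,
    ``locality``, ``region_class``). A taxon absent from a lorica counts as
    a zero contribution, so means are over all *n* loricae of the group.
    Percent statistics are over loricae with nonzero total ballast; loricae
    with zero total are excluded from them with a log entry.
    """
    estimates = estimate_dataset(dataset)
    groups: dict[tuple[str, ...], list[LoricaRecord]] = {}
    for lor in dataset.loricae:
        key = tuple(getattr(lor, g) for g in group_by)
        groups.setdefault(key, []).append(lor)

    summaries = []
    for key, members in groups.items():
        n = len(members)
        taxa = sorted({t for lor in members for t in estimates[lor.lorica_id].mass_by_taxon})
        mass_rows = {
            lor.lorica_id: estimates[lor.lorica_id].mass_by_taxon for lor in members
        }
        totals = [estimates[lor.lorica_id].total for lor in members]
        per_mean, per_sd, occ = {}, {}, {}
        pct_mean, pct_sd = {}, {}
        nonzero_pcts = {
            lor.lorica_id: percent_composition(estimates[lor.lorica_id]) for lor in members
        }
        excluded = [lid for lid, p in nonzero_pcts.items() if p is None]
        if excluded:
            logger.info("group %s: %d zero-ballast loricae excluded from percent stats",
                        key, len(excluded))
        for taxon in taxa:
            vals = [mass_rows[lor.lorica_id].get(taxon, 0.0) for lor in members]
            per_mean[taxon] = float(np.mean(vals))
            per_sd[taxon] = population_sd(vals)
            occ[taxon] = (sum(v > 0 for v in vals), n)
            pvals = [p.get(taxon, 0.0) for p in nonzero_pcts.values() if p is not None]
            if pvals:
                pct_mean[taxon] = float(np.mean(pvals))
                pct_sd[taxon] = population_sd(pvals)
        summaries.append(
            AssemblageSummary(
                key=key, n=n,
                per_taxon_mean=per_mean, per_taxon_sd=per_sd, occurrence=occ,
                total_mean=float(np.mean(totals)), total_sd=population_sd(totals),
                percent_mean=pct_mean, percent_sd=pct_sd,
            )
        )
    summaries.sort(key=lambda s: s.key)
    return summaries


# ---------------------------------------------------------------------------
# Derived comparative metrics

@dataclass(frozen=True)
class ExtraWeight:
    """Ballast expressed as a fraction of bare-lorica dry weight."""

    fraction: float
    percent: float
    percent_nearest5: float
    interval: tuple[float, float]  # fractions at dry weight +sd / -sd


def extra_weight_fraction(ballast_total: float,
                          constants: ConversionConstants | None = None) -> ExtraWeight:
    """Ballast / lorica dry weight, with the dry-weight uncertainty propagated.

    The interval spans ballast/(W+σ) to ballast/(W−σ) for dry weight W ± σ
    (default 40 000 ± 20 000 pg).
    """
    if constants is None:
        constants = ConversionConstants()
    if ballast_total < 0:
        raise ValueError("ballast_total must be >= 0")
    w, sd = constants.lorica_dry_weight, constants.lorica_dry_weight_sd
    frac = ballast_total / w
    lo = ballast_total / (w + sd)
    hi = ballast_total / (w - sd) if w > sd else math.inf
    pct = 100.0 * frac
    return ExtraWeight(
        fraction=frac, percent=pct,
        percent_nearest5=5.0 * round_half_away(pct / 5.0),
        interval=(lo, hi),
    )


def regional_ratio(summary_a: "AssemblageSummary | float",
                   summary_b: "AssemblageSummary | float") -> dict[str, float]:
    """Ratio of group mean total ballast between two assemblages (a / b)."""
    mean_a = summary_a.total_mean if isinstance(summary_a, AssemblageSummary) else float(summary_a)
    mean_b = summary_b.total_mean if isinstance(summary_b, AssemblageSummary) else float(summary_b)
    if mean_b <= 0 or mean_a <= 0:
        raise ZeroDivisionError("regional_ratio requires strictly positive group means")
    return {"ratio": mean_a / mean_b, "mean_a": mean_a, "mean_b": mean_b}


# ---------------------------------------------------------------------------
# Preference matrix

@dataclass(frozen=True)
class PreferenceMatrix:
    """Tintinnid × particle-taxon occurrence fractions and mean mass shares.

    Rows are tintinnid taxa ordered by increasing lorica oral diameter;
    coccolith columns by increasing lith size (taxa without a size key come
    last); diatom columns form a trailing block.
    """

    occurrence: pd.DataFrame
    mass_share: pd.DataFrame
    row_diameters: dict[str, float]


def preference_matrix(datasets: Iterable[StudyDataset]) -> PreferenceMatrix:
    datasets = list(datasets)
    if not datasets:
        raise ValueError("preference_matrix needs at least one dataset")
    reference = datasets[0].reference

    # rows: tintinnid taxa keyed by mean oral diameter
    diam: dict[str, list[float]] = {}
    counts: dict[str, int] = {}
    occ: dict[str, dict[str, int]] = {}
    share_sum: dict[str, dict[str, float]] = {}
    share_n: dict[str, int] = {}
    cocco_taxa: set[str] = set()
    diatom_taxa: set[str] = set()

    for ds in datasets:
        estimates = estimate_dataset(ds)
        for lor in ds.loricae:
            tt = lor.tintinnid_taxon
            counts[tt] = counts.get(tt, 0) + 1
            if lor.oral_diameter is not None:
                diam.setdefault(tt, []).append(lor.oral_diameter)
            est = estimates[lor.lorica_id]
            pct = percent_composition(est) or {}
            if pct:
                share_n[tt] = share_n.get(tt, 0) + 1
            for taxon, pg in est.mass_by_taxon.items():
                if taxon in est.caco3_by_taxon:
                    cocco_taxa.add(taxon)
                else:
                    diatom_taxa.add(taxon)
                if pg > 0:
                    occ.setdefault(tt, {})[taxon] = occ.get(tt, {}).get(taxon, 0) + 1
                share_sum.setdefault(tt, {})[taxon] = (
                    share_sum.get(tt, {}).get(taxon, 0.0) + pct.get(taxon, 0.0) / 100.0
                )

    row_diam = {tt: float(np.mean(v)) for tt, v in diam.items()}
    rows = sorted(counts, key=lambda tt: (row_diam.get(tt, math.inf), tt))
    for tt in counts:
        if tt not in row_diam:
            logger.warning("tintinnid %s has no oral diameter; placed last", tt)

    def _size_key(taxon: str):
        try:
            size = reference.resolve_coccolith(taxon).characteristic_size
        except KeyError:
            size = None
        if size is None:
            logger.warning("coccolith %s has no lith-size key; placed last", taxon)
            return (math.inf, taxon)
        return (size, taxon)

    cocco_cols = sorted(cocco_taxa, key=_size_key)
    diatom_cols = sorted(diatom_taxa)
    cols = cocco_cols + diatom_cols

    occ_df = pd.DataFrame(
        [[occ.get(tt, {}).get(c, 0) / counts[tt] for c in cols] for tt in rows],
        index=rows, columns=cols,
    )
    share_df = pd.DataFrame(
        [
            [
                share_sum.get(tt, {}).get(c, 0.0) / share_n.get(tt, 1)
                for c in cols
            ]
            for tt in rows
        ],
        index=rows, columns=cols,
    )
    return PreferenceMatrix(occurrence=occ_df, mass_share=share_df, row_diameters=row_diam)
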