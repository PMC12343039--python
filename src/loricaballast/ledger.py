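"""Per-lorica particle ledgers: schema, validation, CSV round-trip, fixtures.

A *ledger* records what was counted or measured on each tintinnid lorica.
It consists of two flat tables:

``loricae.csv``
    one row per lorica — id, tintinnid taxon, locality, region class
    (tropical / temperate / polar), optional oral diameter and bowl length
    in μm.

``observations.csv``
    one row per (lorica, particle class) — particle taxon, particle kind
    (coccolith / diatom_fragment / diatom_cell) and a polymorphic quantity:
    a lith ``count``, a direct ``mass_pg``, or a ``biovolume_um3`` still to
    be converted to silica. Published tables print pg for diatoms and
    pg-derived values for some coccoliths, so exact reproduction of survey
    data requires all three quantity types.

Both tables may alternatively live in one CSV with a ``record_type`` column.

Fixture datasets encoding the published per-lorica surveys of four
lorica-agglomerating tintinnids (Codonellopsis cf. soyai, C. pusilla,
Codonella galea, Dictyocysta lepida) ship with the package under
``data/fixtures`` and are addressable by name. Group-summary survey rows
that do not resolve to individual loricae are encoded as pseudo-loricae
carrying the printed mean values; printed totals, occurrence counts
("x of n") and known internal inconsistencies of the printed tables are
kept verbatim in each fixture's ``annotations.json`` rather than silently
"fixed".
"""

from __future__ import annotations

import json
import math
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .reference import ParticleMassReference, builtin_reference, logger

REGION_CLASSES = {"tropical", "temperate", "polar"}
PARTICLE_KINDS = {"coccolith", "diatom_fragment", "diatom_cell"}
QUANTITY_TYPES = {"count", "mass_pg", "biovolume_um3"}

#: quantity types admissible for each particle kind
_VALID_COMBOS = {
    "coccolith": {"count", "mass_pg"},
    "diatom_fragment": QUANTITY_TYPES,
    "diatom_cell": QUANTITY_TYPES,
}

LORICA_COLUMNS = [
    "lorica_id", "tintinnid_taxon", "locality", "region_class",
    "oral_diameter_um", "bowl_length_um",
]
OBSERVATION_COLUMNS = [
    "lorica_id", "particle_taxon", "particle_kind", "quantity_type", "quantity",
]

FIXTURE_NAMES = ("table2", "table3_atlantic", "table3_sots", "table4", "table5")


class LedgerValidationError(ValueError):
    """Ledger failed validation; carries per-row messages."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("ledger validation failed:\n  " + "\n  ".join(problems))


class LoricaRecord(BaseModel):
    model_config = ConfigDict(frozen=True)

    lorica_id: str
    tintinnid_taxon: str
    locality: str
    region_class: str
    oral_diameter: Optional[float] = Field(default=None, gt=0)
    bowl_length: Optional[float] = Field(default=None, gt=0)

    @model_validator(mode="after")
    def _check(self) -> "LoricaRecord":
        if self.region_class not in REGION_CLASSES:
            raise ValueError(
                f"{self.lorica_id}: region_class must be one of {sorted(REGION_CLASSES)}"
            )
        return self


class ParticleObservation(BaseModel):
    model_config = ConfigDict(frozen=True)

    lorica_id: str
    particle_taxon: str
    particle_kind: str
    quantity_type: str
    quantity: float = Field(ge=0)

    @model_validator(mode="after")
    def _check(self) -> "ParticleObservation":
        if self.particle_kind not in PARTICLE_KINDS:
            raise ValueError(f"unknown particle_kind {self.particle_kind!r}")
        if self.quantity_type not in QUANTITY_TYPES:
            raise ValueError(f"unknown quantity_type {self.quantity_type!r}")
        if self.quantity_type not in _VALID_COMBOS[self.particle_kind]:
            raise ValueError(
                f"{self.particle_kind} cannot carry quantity_type {self.quantity_type}"
            )
        if self.quantity_type == "count" and self.quantity != int(self.quantity):
            raise ValueError(f"count quantity must be integer, got {self.quantity}")
        if not math.isfinite(self.quantity):
            raise ValueError("quantity must be finite")
        return self


class StudyDataset(BaseModel):
    """Loricae + observations + the mass reference they resolve against."""

    loricae: list[LoricaRecord]
    observations: list[ParticleObservation]
    reference: ParticleMassReference
    annotations: dict = Field(default_factory=dict)

    def lorica_ids(self) -> list[str]:
        return [lor.lorica_id for lor in self.loricae]

    def observations_for(self, lorica_id: str) -> list[ParticleObservation]:
        return [o for o in self.observations if o.lorica_id == lorica_id]

    def filter(self, *, locality: str | None = None,
               tintinnid_taxon: str | None = None,
               region_class: str | None = None) -> "StudyDataset":
        """Subset by lorica metadata; observations follow their loricae."""
        keep = [
            lor for lor in self.loricae
            if (locality is None or lor.locality == locality)
            and (tintinnid_taxon is None or lor.tintinnid_taxon == tintinnid_taxon)
            and (region_class is None or lor.region_class == region_class)
        ]
        ids = {lor.lorica_id for lor in keep}
        return StudyDataset(
            loricae=keep,
            observations=[o for o in self.observations if o.lorica_id in ids],
            reference=self.reference,
            annotations=self.annotations,
        )

    def validate_integrity(self) -> None:
        """Referential and domain checks beyond per-row schema validation."""
        problems: list[str] = []
        seen: set[str] = set()
        for i, lor in enumerate(self.loricae):
            if lor.lorica_id in seen:
                problems.append(f"loricae row {i + 2}: duplicate lorica_id {lor.lorica_id!r}")
            seen.add(lor.lorica_id)
        for i, obs in enumerate(self.observations):
            row = f"observations row {i + 2}"
            if obs.lorica_id not in seen:
                problems.append(f"{row}: unknown lorica_id {obs.lorica_id!r}")
            if obs.particle_kind == "coccolith" and obs.quantity_type == "count":
                if not self.reference.knows_coccolith(obs.particle_taxon):
                    problems.append(
                        f"{row}: coccolith count for {obs.particle_taxon!r} "
                        "has no reference lith mass or alias"
                    )
            if obs.particle_kind != "coccolith" and obs.quantity_type == "count":
                try:
                    kind = "whole_cell" if obs.particle_kind == "diatom_cell" else "fragment"
                    self.reference.resolve_diatom(obs.particle_taxon, kind)
                except KeyError:
                    problems.append(
                        f"{row}: diatom count for {obs.particle_taxon!r} "
                        "has no reference biovolume"
                    )
        if problems:
            raise LedgerValidationError(problems)


# ---------------------------------------------------------------------------
# CSV I/O

def _loricae_frame(loricae: Iterable[LoricaRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "lorica_id": lor.lorica_id,
                "tintinnid_taxon": lor.tintinnid_taxon,
                "locality": lor.locality,
                "region_class": lor.region_class,
                "oral_diameter_um": lor.oral_diameter,
                "bowl_length_um": lor.bowl_length,
            }
            for lor in loricae
        ],
        columns=LORICA_COLUMNS,
    )


def _observations_frame(observations: Iterable[ParticleObservation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "lorica_id": o.lorica_id,
                "particle_taxon": o.particle_taxon,
                "particle_kind": o.particle_kind,
                "quantity_type": o.quantity_type,
                # counts are written as integers so ledgers diff cleanly
                "quantity": int(o.quantity) if o.quantity_type == "count" else o.quantity,
            }
            for o in observations
        ],
        columns=OBSERVATION_COLUMNS,
    )


def _parse_loricae(df: pd.DataFrame, problems: list[str]) -> list[LoricaRecord]:
    records = []
    for i, row in df.iterrows():
        try:
            records.append(
                LoricaRecord(
                    lorica_id=str(row["lorica_id"]),
                    tintinnid_taxon=str(row["tintinnid_taxon"]),
                    locality=str(row["locality"]),
                    region_class=str(row["region_class"]),
                    oral_diameter=None if pd.isna(row.get("oral_diameter_um")) else float(row["oral_diameter_um"]),
                    bowl_length=None if pd.isna(row.get("bowl_length_um")) else float(row["bowl_length_um"]),
                )
            )
        except Exception as exc:  # pydantic ValidationError or cast failure
            problems.append(f"loricae row {i + 2}: {exc}")
    return records


def _parse_observations(df: pd.DataFrame, problems: list[str]) -> list[ParticleObservation]:
    records = []
    for i, row in df.iterrows():
        try:
            records.append(
                ParticleObservation(
                    lorica_id=str(row["lorica_id"]),
                    particle_taxon=str(row["particle_taxon"]),
                    particle_kind=str(row["particle_kind"]),
                    quantity_type=str(row["quantity_type"]),
                    quantity=float(row["quantity"]),
                )
            )
        except Exception as exc:
            problems.append(f"observations row {i + 2}: {exc}")
    return records


def read_ledger(path: str | Path,
                reference: ParticleMassReference | None = None) -> StudyDataset:
    """Read a ledger from a directory (two CSVs) or a single combined CSV.

    A directory must contain ``loricae.csv`` and ``observations.csv`` and may
    contain ``annotations.json``. A single file must carry a ``record_type``
    column with values ``lorica`` / ``observation``. The returned dataset has
    passed schema and referential validation against *reference* (builtin by
    default); any violation raises :class:`LedgerValidationError` naming the
    offending rows.
    """
    if reference is None:
        reference = builtin_reference()
    path = Path(path)
    annotations: dict = {}
    problems: list[str] = []
    if path.is_dir():
        lor_df = pd.read_csv(path / "loricae.csv", comment="#")
        obs_path = path / "observations.csv"
        if obs_path.stat().st_size > 0:
            obs_df = pd.read_csv(obs_path, comment="#")
            if obs_df.empty or "lorica_id" not in obs_df.columns:
                obs_df = pd.DataFrame(columns=OBSERVATION_COLUMNS)
        else:
            obs_df = pd.DataFrame(columns=OBSERVATION_COLUMNS)
        ann_path = path / "annotations.json"
        if ann_path.exists():
            annotations = json.loads(ann_path.read_text())
    elif path.is_file():
        df = pd.read_csv(path, comment="#")
        if "record_type" not in df.columns:
            raise LedgerValidationError(
                [f"{path}: single-file ledger requires a 'record_type' column"]
            )
        lor_df = df[df["record_type"] == "lorica"].reset_index(drop=True)
        obs_df = df[df["record_type"] == "observation"].reset_index(drop=True)
    else:
        raise FileNotFoundError(path)

    loricae = _parse_loricae(lor_df, problems)
    observations = _parse_observations(obs_df, problems)
    if problems:
        raise LedgerValidationError(problems)
    ds = StudyDataset(
        loricae=loricae, observations=observations,
        reference=reference, annotations=annotations,
    )
    ds.validate_integrity()
    logger.debug("read ledger %s: %d loricae, %d observations",
                 path, len(loricae), len(observations))
    return ds


def write_ledger(dataset: StudyDataset, path: str | Path) -> list[Path]:
    """Write a dataset to *path*.

    If *path* ends in ``.csv`` a single combined file with a ``record_type``
    column is produced; otherwise *path* is treated as a directory receiving
    ``loricae.csv``, ``observations.csv`` and (if present) ``annotations.json``.
    ``read_ledger(write_ledger(d))`` reproduces *d*'s values exactly.
    """
    path = Path(path)
    written: list[Path] = []
    lor_df = _loricae_frame(dataset.loricae)
    obs_df = _observations_frame(dataset.observations)
    if path.suffix == ".csv":
        lor_df.insert(0, "record_type", "lorica")
        obs_df.insert(0, "record_type", "observation")
        combined = pd.concat([lor_df, obs_df], ignore_index=True)
        path.parent.mkdir(parents=True, exist_ok=True)
        combined.to_csv(path, index=False)
        written.append(path)
    else:
        path.mkdir(parents=True, exist_ok=True)
        lor_df.to_csv(path / "loricae.csv", index=False)
        obs_df.to_csv(path / "observations.csv", index=False)
        written += [path / "loricae.csv", path / "observations.csv"]
        if dataset.annotations:
            (path / "annotations.json").write_text(
                json.dumps(dataset.annotations, indent=1, sort_keys=True)
            )
            written.append(path / "annotations.json")
    return written


def load_fixture(name: str,
                 reference: ParticleMassReference | None = None) -> StudyDataset:
    """Load a packaged survey fixture by name.

    Available names: ``table2`` (Codonellopsis cf. soyai, Kerguelen Plateau,
    11 loricae), ``table3_atlantic`` / ``table3_sots`` (C. pusilla lorica-type
    groups), ``table4`` (Codonella galea, Tonga + Coral Sea), ``table5``
    (Dictyocysta lepida, three regions).
    """
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}")
    with resources.as_file(
        resources.files("loricaballast").joinpath(f"data/fixtures/{name}")
    ) as p:
        return read_ledger(p, reference)
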