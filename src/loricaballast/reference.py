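"""Literature-derived particle mass reference tables and conversion formulas.

Tintinnid loricae agglomerate two classes of biomineral particle whose mass
must be accounted differently:

* **Coccoliths** — single calcite plates shed by coccolithophorid algae.
  Each taxon has a characteristic per-lith CaCO3 mass (pg), so a lith count
  converts directly to mass: ``mass = count * lith_mass``.
* **Diatom fragments / cells** — siliceous debris whose mass is reached via
  geometry: a characteristic biovolume (μm³) is converted to biogenic silica
  at 0.0005 pmol Si per μm³ and 28 pg Si per pmol (0.014 pg/μm³).

Taxa that appear in survey data without a published per-lith mass
(e.g. *Gephyrocapsa*, *Coronosphaera*, *Alisphaera*) are resolved through an
explicit, user-editable alias table rather than silently guessed; aliases
map to a morphologically analogous reference taxon. *Umbellosphaera* and
*Calciosolenia* deliberately carry no default mass at all — their
contributions must be recorded as pg directly.
"""

from __future__ import annotations

import logging
import math
from importlib import resources
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

logger = logging.getLogger("loricaballast")

# Mass of a single coccolith in pg CaCO3 equals count-to-mass slope w;
# fragment silica follows mass = biovolume * SI_PMOL_PER_UM3 * SI_PG_PER_PMOL.
SI_PMOL_PER_UM3_DEFAULT = 0.0005
SI_PG_PER_PMOL_DEFAULT = 28.0
LORICA_DRY_WEIGHT_PG_DEFAULT = 40_000.0
LORICA_DRY_WEIGHT_SD_PG_DEFAULT = 20_000.0

#: Literature sinking-rate range for loricate tintinnids (m/day); documented
#: context only, never used in any computation here.
SINKING_RATE_RANGE_M_PER_DAY = (0.25, 15.9)

SHAPE_CLASSES = {
    "placolith-discoidal",
    "placolith-ellipsoidal",
    "prolate-rhabdolith",
    "lath-like",
    "funnel",
}


class CoccolithSpec(BaseModel):
    """One coccolithophorid taxon: per-lith CaCO3 mass and lith geometry."""

    model_config = ConfigDict(frozen=True)

    taxon: str
    lith_mass: float = Field(gt=0, description="pg CaCO3 per lith")
    lith_size: Optional[tuple[float, float]] = Field(
        default=None, description="lith length/diameter range in μm (min, max)"
    )
    shape_class: Optional[str] = None
    source: str = ""

    @model_validator(mode="after")
    def _check(self) -> "CoccolithSpec":
        if self.lith_size is not None:
            lo, hi = self.lith_size
            if not (0 < lo <= hi):
                raise ValueError(f"{self.taxon}: invalid lith_size range {self.lith_size}")
        if self.shape_class is not None and self.shape_class not in SHAPE_CLASSES:
            raise ValueError(f"{self.taxon}: unknown shape_class {self.shape_class!r}")
        return self

    @property
    def characteristic_size(self) -> Optional[float]:
        """Midpoint of the lith size range (sort key for preference matrices)."""
        if self.lith_size is None:
            return None
        return 0.5 * (self.lith_size[0] + self.lith_size[1])


class DiatomParticleSpec(BaseModel):
    """One diatom particle class (fragment or whole cell) with its biovolume."""

    model_config = ConfigDict(frozen=True)

    taxon: str
    particle_kind: str = Field(pattern="^(fragment|whole_cell)$")
    biovolume: float = Field(gt=0, description="μm³ per particle")


class ConversionConstants(BaseModel):
    """Silica conversion constants and the reference lorica dry weight."""

    model_config = ConfigDict(frozen=True)

    si_pmol_per_um3: float = Field(default=SI_PMOL_PER_UM3_DEFAULT, gt=0)
    si_pg_per_pmol: float = Field(default=SI_PG_PER_PMOL_DEFAULT, gt=0)
    lorica_dry_weight: float = Field(default=LORICA_DRY_WEIGHT_PG_DEFAULT, gt=0)
    lorica_dry_weight_sd: float = Field(default=LORICA_DRY_WEIGHT_SD_PG_DEFAULT, gt=0)

    @property
    def si_pg_per_um3(self) -> float:
        return self.si_pmol_per_um3 * self.si_pg_per_pmol


class UnknownTaxonError(KeyError):
    """A particle taxon with no mass entry and no alias."""

    def __init__(self, taxon: str, kind: str = "coccolith"):
        self.taxon = taxon
        super().__init__(f"unknown {kind} taxon {taxon!r}: no reference mass and no alias")


class ParticleMassReference(BaseModel):
    """Aggregated mass reference: coccoliths, diatom particles, constants, aliases."""

    coccoliths: dict[str, CoccolithSpec]
    diatoms: dict[tuple[str, str], DiatomParticleSpec]
    constants: ConversionConstants = ConversionConstants()
    aliases: dict[str, str] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _check(self) -> "ParticleMassReference":
        for alias, target in self.aliases.items():
            if target not in self.coccoliths:
                raise ValueError(f"alias {alias!r} targets unknown taxon {target!r}")
            if alias in self.coccoliths:
                raise ValueError(f"alias {alias!r} duplicates an existing coccolith entry")
        for key, spec in self.diatoms.items():
            if key != (spec.taxon, spec.particle_kind):
                raise ValueError(f"diatom key {key} does not match spec {spec.taxon}/{spec.particle_kind}")
        return self

    def resolve_coccolith(self, taxon: str) -> CoccolithSpec:
        if taxon in self.coccoliths:
            return self.coccoliths[taxon]
        if taxon in self.aliases:
            target = self.aliases[taxon]
            logger.debug("alias resolution: %s -> %s", taxon, target)
            return self.coccoliths[target]
        raise UnknownTaxonError(taxon)

    def resolve_diatom(self, taxon: str, particle_kind: str) -> DiatomParticleSpec:
        key = (taxon, particle_kind)
        if key in self.diatoms:
            return self.diatoms[key]
        raise UnknownTaxonError(f"{taxon}/{particle_kind}", kind="diatom")

    def knows_coccolith(self, taxon: str) -> bool:
        return taxon in self.coccoliths or taxon in self.aliases

    # -- serialization ------------------------------------------------------

    def to_config(self) -> dict:
        return {
            "coccoliths": {
                t: {
                    "lith_mass": s.lith_mass,
                    "lith_size": list(s.lith_size) if s.lith_size else None,
                    "shape_class": s.shape_class,
                    "source": s.source,
                }
                for t, s in self.coccoliths.items()
            },
            "diatom_particles": {
                f"{t}/{k}": {"biovolume": s.biovolume} for (t, k), s in self.diatoms.items()
            },
            "constants": self.constants.model_dump(),
            "aliases": dict(self.aliases),
        }

    @classmethod
    def from_config(cls, cfg: dict) -> "ParticleMassReference":
        coccoliths = {}
        for taxon, entry in cfg.get("coccoliths", {}).items():
            if isinstance(entry, (int, float)):
                entry = {"lith_mass": entry}
            size = entry.get("lith_size")
            coccoliths[taxon] = CoccolithSpec(
                taxon=taxon,
                lith_mass=entry["lith_mass"],
                lith_size=tuple(size) if size else None,
                shape_class=entry.get("shape_class"),
                source=entry.get("source", ""),
            )
        diatoms = {}
        for key, entry in cfg.get("diatom_particles", {}).items():
            if isinstance(entry, (int, float)):
                entry = {"biovolume": entry}
            taxon, _, kind = key.partition("/")
            kind = kind or "fragment"
            diatoms[(taxon, kind)] = DiatomParticleSpec(
                taxon=taxon, particle_kind=kind, biovolume=entry["biovolume"]
            )
        constants = ConversionConstants(**cfg.get("constants", {}))
        return cls(
            coccoliths=coccoliths,
            diatoms=diatoms,
            constants=constants,
            aliases=dict(cfg.get("aliases", {})),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_config(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "ParticleMassReference":
        return cls.from_config(yaml.safe_load(Path(path).read_text()))


def builtin_reference() -> ParticleMassReference:
    """The packaged default mass reference.

    Loads ``data/reference_default.yaml`` shipped with the package; the YAML
    file is the single source of truth so users can copy and edit it.
    """
    with resources.as_file(
        resources.files("loricaballast").joinpath("data/reference_default.yaml")
    ) as p:
        return ParticleMassReference.load(p)


def lith_mass(taxon: str, reference: ParticleMassReference) -> float:
    """Per-lith CaCO3 mass (pg) for a coccolith taxon, via alias if needed."""
    return reference.resolve_coccolith(taxon).lith_mass


def fragment_silica_mass(biovolume: float, constants: ConversionConstants | None = None) -> float:
    """Convert a siliceous biovolume (μm³) to biogenic silica mass (pg).

    With the defaults, 0.0005 pmol Si/μm³ × 28 pg Si/pmol = 0.014 pg/μm³,
    so 100 μm³ corresponds to 1.4 pg silica.
    """
    if constants is None:
        constants = ConversionConstants()
    if not math.isfinite(biovolume) or biovolume < 0:
        raise ValueError(f"biovolume must be finite and >= 0, got {biovolume}")
    return biovolume * constants.si_pg_per_um3
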