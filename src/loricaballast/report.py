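"""Run configuration, report rendering, and the end-to-end analysis driver."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import __version__
from .ledger import StudyDataset, load_fixture, read_ledger
from .pipeline import (
    AssemblageSummary,
    ClassificationPolicy,
    classify_lorica,
    estimate_dataset,
    preference_matrix,
    round_half_away,
    summarize_assemblage,
)
from .reference import ParticleMassReference, builtin_reference, logger


class RunConfig(BaseModel):
    """Configuration of one full analysis run."""

    input_path: Optional[str] = None
    fixture: Optional[str] = None
    reference_path: Optional[str] = None
    group_by: tuple[str, ...] = ("tintinnid_taxon", "locality")
    out_dir: str = "ballast_out"
    seed: int = 0
    verbosity: str = "INFO"

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        if (self.input_path is None) == (self.fixture is None):
            raise ValueError("exactly one of input_path / fixture must be set")
        return self

    def config_hash(self) -> str:
        # hash only what affects results, not where they land on disk
        payload = json.dumps(
            self.model_dump(exclude={"out_dir", "verbosity"}), sort_keys=True
        ).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def _load(config: RunConfig) -> StudyDataset:
    reference: ParticleMassReference | None = None
    if config.reference_path:
        reference = ParticleMassReference.load(config.reference_path)
    if config.fixture:
        return load_fixture(config.fixture, reference)
    return read_ledger(config.input_path, reference)


def _provenance(config: RunConfig) -> str:
    return (f"# loricaballast {__version__} | config {config.config_hash()} "
            f"| seed {config.seed}\n")


def _fmt_pm(mean: float, sd: float) -> str:
    return f"{round_half_away(mean)} ± {round_half_away(sd)}"


def render_summary_table(
    summaries: Sequence[AssemblageSummary],
    reference: ParticleMassReference | None = None,
) -> pd.DataFrame:
    """Group summaries as one table mirroring the published survey layout.

    Coccolith columns are ordered by increasing per-lith mass, then diatom
    and unresolvable taxa alphabetically; cells are "mean ± sd" (integer pg,
    half away from zero) or "x of n" for occurrence-only taxa.
    """
    if not summaries:
        raise ValueError("render_summary_table needs at least one summary")
    if reference is None:
        reference = builtin_reference()

    taxa = sorted({t for s in summaries for t in s.per_taxon_mean})

    def _order(taxon: str):
        try:
            return (0, reference.resolve_coccolith(taxon).lith_mass, taxon)
        except KeyError:
            return (1, 0.0, taxon)

    taxa.sort(key=_order)
    rows = []
    for s in summaries:
        row: dict[str, object] = {"group": " / ".join(s.key), "n": s.n}
        for t in taxa:
            if t in s.per_taxon_mean:
                row[t] = _fmt_pm(s.per_taxon_mean[t], s.per_taxon_sd[t])
                row[f"{t} occurrence"] = s.occurrence_str(t)
        row["total"] = _fmt_pm(s.total_mean, s.total_sd)
        rows.append(row)
    cols = ["group", "n"]
    for t in taxa:
        cols += [t, f"{t} occurrence"]
    cols.append("total")
    return pd.DataFrame(rows, columns=cols)


def run_full_analysis(config: RunConfig) -> dict[str, Path]:
    """compute → classify → summarize → matrix; write the full report bundle.

    Writes per-lorica ballast, group summary, preference-matrix CSVs and a
    markdown report into ``config.out_dir``; returns the paths keyed by
    artifact name. Deterministic: identical config and inputs give
    byte-identical outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset = _load(config)
    reference = dataset.reference
    header = _provenance(config)
    paths: dict[str, Path] = {}

    # per-lorica ballast + classification
    estimates = estimate_dataset(dataset)
    policy = ClassificationPolicy()
    obs_by = {lor.lorica_id: dataset.observations_for(lor.lorica_id)
              for lor in dataset.loricae}
    rows = []
    for lor in dataset.loricae:
        est = estimates[lor.lorica_id]
        label = classify_lorica(est, obs_by[lor.lorica_id], policy, reference)
        row = {
            "lorica_id": lor.lorica_id,
            "tintinnid_taxon": lor.tintinnid_taxon,
            "locality": lor.locality,
            "caco3_pg": est.caco3_total,
            "silica_pg": est.silica_total,
            "total_pg": est.total,
            "total_pg_rounded": round_half_away(est.total),
            "label": label.label,
            "dominant_share": label.dominant_share,
        }
        rows.append(row)
    ballast_df = pd.DataFrame(rows)
    paths["ballast"] = out / "ballast_per_lorica.csv"
    with open(paths["ballast"], "w") as fh:
        fh.write(header)
        ballast_df.to_csv(fh, index=False)

    # group summaries
    summaries = summarize_assemblage(dataset, config.group_by)
    summary_df = render_summary_table(summaries, reference)
    paths["summary"] = out / "group_summary.csv"
    with open(paths["summary"], "w") as fh:
        fh.write(header)
        summary_df.to_csv(fh, index=False)

    # preference matrix
    matrix = preference_matrix([dataset])
    paths["matrix"] = out / "preference_matrix.csv"
    with open(paths["matrix"], "w") as fh:
        fh.write(header)
        matrix.occurrence.to_csv(fh, index_label="tintinnid_taxon")

    # markdown report
    md = [header.replace("# ", "<!-- ").rstrip() + " -->", "",
          "# Lorica ballast report", "",
          f"Loricae: {len(dataset.loricae)}; observations: {len(dataset.observations)}",
          "", "## Group summaries", "", "```",
          summary_df.to_string(index=False), "```",
          "", "## Per-lorica ballast", "", "```",
          ballast_df.round(2).to_string(index=False), "```", ""]
    paths["report"] = out / "report.md"
    paths["report"].write_text("\n".join(md))
    logger.info("report bundle written to %s", out)
    return paths
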