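# Methods

## The mass model

Ballast on an agglomerated tintinnid lorica is additive over the particles
counted or measured on it:

    B = Σ_i n_i · w_i + Σ_j V_j · c          [pg per lorica]

Coccolith taxa contribute lith count × per-lith CaCO₃ mass `w_i`; diatom
particles contribute biovolume × the silica conversion
`c = si_pmol_per_um3 · si_pg_per_pmol` (defaults 0.0005 pmol μm⁻³ and
28 pg pmol⁻¹, i.e. 0.014 pg μm⁻³). The model assumes particles do not
overlap enough to be double-counted, that a micrograph of one lateral face
generalizes to the whole lorica, and that every lith of a taxon has the
taxon's characteristic mass (no intra-specific morphotype discrimination).
These are the assumptions under which the per-lith masses and fragment
biovolumes were published; the package does not try to improve on them.

Ledgers are deliberately polymorphic in quantity type (`count`, `mass_pg`,
`biovolume_um3`). Published tables print pg for diatoms and pg-derived
values for some coccoliths; insisting on counts would make exact encoding
of printed data impossible. `mass_pg` entries bypass the reference tables
entirely, which is also the escape hatch for taxa with no published
per-lith mass (*Umbellosphaera*, *Calciosolenia*): the package refuses to
invent masses for them.

## Reference tables and aliases

All constants live in `data/reference_default.yaml` and are overridable via
`--reference` / `ParticleMassReference.load`, so sensitivity analyses need
no code changes. Taxa that appear in survey data without a published mass
are resolved through an explicit alias table by morphological analogy
(*Gephyrocapsa* → *Emiliania*-size placoliths, *Coronosphaera* →
*Syracosphaera*, *Alisphaera* → *Emiliania*). Aliases are user-editable and
logged on resolution; an unknown taxon without an alias is a hard error
naming the taxon and row.

## Summary statistics

Group summaries use the arithmetic mean and the **population** standard
deviation (divisor *n*). This is an empirical decision, not a stylistic
one: the published per-lorica survey summaries only reproduce under
n-division (the Kerguelen Emiliania column gives sd 461 with *n*, 483 with
*n−1*). A lorica lacking a taxon counts as a zero contribution, so means
are over all *n* loricae of a group; occurrence "x of n" counts loricae
with any strictly positive quantity. Display rounding is half-away-from-
zero to integer pg and percent; unrounded values are always retained on the
objects. Percent composition of a zero-ballast lorica is reported as
undefined (`None`), never as a division error.

## Fixtures and printed-table discrepancies

The packaged fixtures encode the published tables as faithfully as the
printed page allows:

* Coccolith cells printed as pg are stored as lith counts when the value is
  an exact multiple of the reference per-lith mass, otherwise as `mass_pg`.
* Tables whose rows are group summaries rather than individual loricae are
  encoded as pseudo-loricae carrying the printed mean values (one per
  group, or *n* replicates where occurrence arithmetic requires it), with
  the printed totals and sds kept in `annotations.json`.
* Rows whose printed components do not sum to their printed total are
  flagged in a machine-readable `known_discrepancies` list with both
  values; tests assert the flagged rows against their component sums and
  everything else against the printed totals within ±1 pg. Nothing is
  silently corrected.
* Occurrence-only cells ("6 of 11") are dataset-level annotations, never
  expanded into invented per-lorica observations.

## Classification

A lorica is labelled `diatom-type` if it carries any whole diatom cell,
else `<taxon>-dominated` if a heavy coccolith taxon (default list
{Calcidiscus, Coccolithus}) holds ≥ 50% of total ballast mass, else
`other`. The source surveys name these types without stating cutoffs, so
both the heavy-taxon list and the threshold are policy parameters.
Dominance ties break by larger share, then heavier per-lith mass, then
lexicographic order, with a log entry.

## The synthetic generator

`simulate_dataset` emulates the features of real agglomeration data the
pipeline must survive, and only those:

* **Ambient pools** per region class, with relative abundances and
  characteristic particle sizes. Defaults: polar pools dominated by
  Emiliania liths plus diatom fragments; temperate pools adding
  Calcidiscus/Coccolithus/Helicosphaera; tropical pools with
  Umbilicosphaera, Florisphaera, Syracosphaera, Rhabdosphaera. Sizes use
  the stated lith lengths (Emiliania 3–4 μm, Calcidiscus 9 μm,
  Helicosphaera 6–12 μm, Rhabdosphaera up to 12 μm); abundances are
  plausible rank orders for each region, chosen once, not fitted.
* **Size-selective capture**: particle *i* is drawn with weight
  ∝ abundance × (1 + strength) when its size is 20–30% of the lorica oral
  diameter, ∝ abundance otherwise. A multiplicative boost rather than a
  hard filter, because real loricae carry small and large liths
  simultaneously; strength 0 recovers ambient proportions exactly, which
  anchors the calibration tests. Whether the published 20–30% prey-size
  preference really governs agglomerated (as opposed to ingested)
  particles is an open question; the window and strength are parameters,
  not claims.
* **Scarcity shift**: when coccolith availability falls below a threshold,
  coccolith abundances are multiplied by the availability scalar and the
  pool renormalized — at availability 0 capture is diatoms only. This
  reproduces the observed binary coccolith-rich vs fragment-only pattern
  without asserting a mechanism.
* Particle counts per lorica are Poisson by default (negative binomial
  with dispersion `k` available for overdispersion); oral diameters are
  normal, truncated at 1 μm. The surveys give no count model; Poisson is
  the minimal choice and the recovery harness makes its consequences
  visible.

All randomness flows from one `numpy.random.default_rng(seed)`; identical
parameters give byte-identical ledgers.

What the generator does **not** emulate: spatial arrangement of particles
on the bowl, hydrodynamic sorting, lorica construction kinetics,
measurement error in biovolume estimation, or correlation between lorica
size and particle load beyond the selectivity window. Passing tests on
synthetic data therefore demonstrate that the accounting, summaries and
selectivity machinery are correct — not that real capture follows this
model.

## Recovery harness

`recovery_experiment` compares the pipeline's mean total ballast over a
simulated dataset against the closed form E[B] = E[count] × Σ p_i·m_i,
with capture weights evaluated at the mean oral diameter, and reports
z = (observed − expected)/SE. The expectation is exact for selectivity
strength 0 (weights independent of diameter) and an approximation
otherwise. Across seeds the z-scores are standard-normal to good
approximation; single-seed checks use |z| < 3. Problem sizes in the test
suite — 200 loricae × ~100 particles for recovery, ≥10 000 particles for
the non-selective convergence bound, 500 loricae for the scarcity-shift
limit — keep every statistical check comfortably stable while the full
suite runs in seconds.

## Numerical choices and degenerate inputs

* Conservation (`total = Σ` components) is exact floating-point addition;
  tests use 1e-9 relative tolerance.
* Rounding for display: half away from zero (`round_half_away`), because
  banker's rounding would contradict several printed cells.
* Zero-total loricae: excluded from percent statistics with a log entry;
  zero-ballast groups raise on ratio computation rather than returning
  infinity.
* Degenerate ambient pools (all-zero abundance, or a scarcity shift that
  empties the pool) are rejected at construction.
* Preference-matrix sort keys: tintinnid rows by mean oral diameter,
  coccolith columns by lith-size midpoint; taxa missing a key are placed
  last with a warning rather than dropped.

## Known limitations

* Per-lith masses are point values; no uncertainty is propagated through
  the CaCO₃ sums (only the bare-lorica dry weight carries an explicit ±).
* Group-summary tables encoded as pseudo-loricae support occurrence and
  annotation arithmetic but cannot recover the true per-lorica variance of
  those populations.
* The alias masses for taxa without published values are analogies, not
  measurements; any analysis sensitive to them should re-run with a custom
  reference file.
* Region classes are a three-way label (tropical/temperate/polar); no
  temperature or viscosity covariate is modelled.
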