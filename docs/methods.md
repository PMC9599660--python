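# Methods

## Model formulation

The core object is a stoichiometric model augmented with one aggregate
proteome constraint.  Flux balance analysis solves

    max  cᵀ v
    s.t. S v = 0
         lb ≤ v ≤ ub
         Σ_i v_i · MW_i / (σ_i · k_cat,i) ≤ P_total · f        (pool row)

over fluxes v (mmol/gDCW/h).  Units are locked package-wide: MW in kDa
(≡ g/mmol), k_cat stored in h⁻¹, so each pool term is g enzyme/gDCW and
the bound P_total·f is g protein/gDCW.  No pseudo-metabolites or
pseudo-reactions are added; the pool is a single inequality appended to
the LP.  This keeps the base stoichiometry inspectable and makes the
enzyme constraint trivially removable (set f = 1, P_total large) for
containment and limit checks.

The pool row is only meaningful on a *fully split* model: reversible
reactions are divided into forward and `_reverse` halves (different
directions can have different turnover numbers) and isozyme-catalyzed
reactions into `_num1`…`_numk` copies (each isozyme has its own MW and
k_cat).  Splitting is flux-space-neutral: any feasible state of the
original maps to one of the split model with identical net fluxes, which
the tests verify by LP in both directions.  Exchange reactions keep their
native signed bounds, are never split, and never carry enzyme: they are
bookkeeping for the environment, not catalyzed conversions.  A reaction
whose GPR, EC annotation or k_cat is missing stays outside the pool and is
reported in an "unconstrained" list rather than being guessed at.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| P_total | 0.56 | g protein/gDCW | total cellular protein content, typical for microbes |
| f | computed (or supplied) | – | mass fraction of measured protein encoded by model genes, f = Σ_model A·MW / Σ_measured A·MW |
| σ | 0.5 | – | average in-vivo saturation of enzymes; discounts in-vitro k_cat |
| k_cat | from kinetics table | s⁻¹ in, h⁻¹ internal | turnover number per (reaction, direction, enzyme) |
| MW | Σ_j N_j·MW_j | kDa | complex weight from subunit copy numbers N_j and monomer weights |

f is applied to whatever abundance proxy the user supplies (transcript or
protein); no transcript→protein conversion is attempted.

## Subunit stoichiometry

Oligomeric-state text is parsed by a fixed pattern table, not free NLP:
`Homo<k>mer` → k copies of one species; `Hetero<k>mer` → k total, species
unknown; `<K>mer of n1 X and n2 Y chains/subunits` → labelled counts; bare
`<k>mer` → k total; anything else defaults to a monomer **with a flag**.
Flags propagate into the enzyme table so every assumed stoichiometry is
auditable.  Mapping per-protein totals onto the genes of a complex uses
one rule: a single-gene enzyme takes its own total; a complex of m genes
whose members agree on a total T divisible by m takes T/m each (the
heterotetramer of two alpha and two beta chains gives each of its two
genes N = 2); anything else falls back to one copy per gene, flagged
"stoichiometry unknown".  Guessing hidden stoichiometry would silently
corrupt MW, which is precisely the failure mode this package exists to
avoid.

## GPR curation

GPR text is normalized to disjunctive normal form with sorted gene ids and
deduplicated complexes, giving a deterministic enzyme order that downstream
splitting relies on.  The `and`-pair screen computes global
(Needleman–Wunsch) percent identity under BLOSUM62 with affine gaps (open
10, extend 0.5), identity = identical columns / alignment columns.  Pairs
above the 20% operating threshold are reported as *suspect* — likely
isozymes mis-encoded as complexes — with the threshold strict (> not ≥)
and exposed as a parameter.  The screen only reports; edits are applied by
an explicit, logged operation, mirroring how curation is actually done
(automated flagging, manual confirmation).  Pairs lacking a sequence are
reported as "unscreened" rather than dropped.

## k_cat matching and calibration

Matching searches the local kinetics table at three levels in strict
priority: exact EC + organism, exact EC any organism, EC with the last
field wildcarded.  Within the first non-empty level the default aggregate
is the **maximum** (configurable to median): σ = 0.5 already discounts
saturation, and the calibration step itself substitutes class maxima, so a
conservative initial pick would only shift work into calibration.

Calibration raises one k_cat per round: solve pFBA for growth under fixed
uptake, rank constrained reactions by enzyme-cost share
v·MW/(σ·k_cat)/pool, and replace the top-ranked raisable reaction's k_cat
with the class-level table maximum.  Ties break lexicographically on
reaction id, so runs are deterministic.  A reaction already at its class
maximum is never re-selected; the loop stops at the target growth, the
round budget, or candidate exhaustion.  Growth is non-decreasing across
rounds (raising a k_cat only relaxes the LP).  Manual overrides use the
same substitution mechanics and are provenance-stamped.

## Numerical choices

All LPs are solved with HiGHS (via `scipy.optimize.linprog`) at 1e-9
primal/dual feasibility tolerances.  pFBA is a two-stage LP: maximize the
objective, then constrain it to its optimum (1e-9 relative slack) and
minimize Σ|v|; on a split model only exchanges can run negative, and those
get auxiliary absolute-value variables.  E_min minimizes the pool
expression itself subject to fixed fluxes.  Infeasible or unbounded
programs are reported as such in the solution status — never as silent
zeros.  Values are rounded only at I/O.

Flux-variability aggregation back onto the original network: isozyme
copies contribute the widest member range; for reversible pairs the
reverse range is subtracted from the forward range, exactly as specified
by the range arithmetic, with a guard — a negative result is emitted
verbatim with a `review` flag, because subtracting ranges can undershoot
and silently clipping would hide it.  "Active" reactions are |v| > 1e-6 in
the parsimonious reference solution; "completely variable" means the range
spans ≥ 99.9% of the bound span.  Both cutoffs are package choices.

The engineering-target scenarios fix growth (high-growth 0.46 h⁻¹ vs
low-growth 0.1 h⁻¹ by default), maximize the product exchange, then
resolve residual degeneracy by minimizing total enzyme at the product
optimum, so the per-reaction costs that enter the fold-change
classification come from a unique flux state.  The fold threshold (1.5) is
inclusive (≥).  Zero-denominator folds classify at infinity and are
flagged.  The biomass-yield constant is 0.18016 g/mmol glucose.

The metabolite-identifier normalizer applies substitutions longest pattern
first — "(e)" → "_e", then "-D"/"-L"/"-R" → "__D"/"__L"/"__R", then any
residual "-" → "_" — so a trailing "-D(e)" cannot be corrupted; reaction
ids map every "-" to "__" regardless of an "EX" prefix (the two published
bullet rules are identical as printed; if a single "_" was ever intended
for non-exchange reactions, that is not recoverable from the rule text, so
the printed rule is implemented and noted here).

## The synthetic fixtures

`synthetic_fixtures` generates the complete input set at toy scale
(~12–15 reactions, 9 proteins): model JSON, protein TSV, kinetics TSV,
abundance TSV, plus a ground-truth record.  The topology is the minimal
architecture that produces overflow metabolism: a respiration-like branch
with high biomass yield y₁ and high enzyme cost a₁ per unit flux, and a
fermentation-like branch with y₂ < y₁, a₂ < a₁ and an acetate-like
byproduct, with parameters constrained so the fermentative branch is the
more enzyme-efficient one (y₂/a₂ > y₁/a₁).  Under those conditions the
optimal-growth LP reduces to two variables and is solved in closed form by
`overflow_switch_oracle`: pure respiration up to u* = pool/a₁, then a mix
with both the uptake and the pool constraint binding, byproduct rising
linearly, growth slope dropping to the fermentative margin.  Defaults
place the switch near 4.5 mmol/gDCW/h with respiratory growth ≈ 0.1 h⁻¹
per unit uptake, i.e. growth rates around 0.45 h⁻¹ at ~4.5–5 uptake —
realistic magnitudes for a glucose-grown bacterium; per-seed jitter (±10%
on yields and switch point) keeps property tests from overfitting one
arithmetic instance.  f is 0.46 by construction of the abundance table
(two abundant non-model proteins carry the remaining mass), so
pool = 0.56 × 0.46 = 0.2576 g/gDCW.

The fixtures also embed the curation edge cases on purpose: a
heterotetrameric complex whose text gives labelled 2+2 counts, a
homodimer, one deliberately unparseable oligomer description, an isozyme
pair with ≥ 80% identical sequences (built by single-site mutation, so
identity has a counting oracle), a reversible transporter, a reaction with
an EC absent from the kinetics table, and — in the calibration variant — a
respiration k_cat entered 10× too small with the true value present at
class level, making the expected calibration trajectory (one round, known
final growth) exact.

What the fixtures do **not** emulate: genome-scale combinatorics,
cofactor/energy stoichiometry, thermodynamic direction constraints,
measurement noise in abundances, and the heavy-tailed k_cat coverage of
real databases.  Passing tests therefore demonstrate that the machinery is
correct on networks where the answer is provable, not that any particular
organism's published numbers are reproduced; those require the user's own
model, kinetics and abundance files, which the same pipeline accepts.

## Known limitations

* One aggregate pool; no per-enzyme proteomics bounds and no
  MOMA/ROOM-style perturbation analyses.
* k_cat gaps are reported, not imputed (no ML fill-in).
* The and/or screen is pairwise; higher-order mis-specified complexes are
  only caught pair by pair.
* Range subtraction for reversible pairs can be negative (flagged, see
  above); interpreting such rows needs the member ranges, which are kept
  in the output.
* SBML round-tripping relies on cobrapy and inherits its handling of
  annotation corner cases.
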