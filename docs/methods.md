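# Methods

## Scope and data model

The package analyses transect-based biomass inventories of
post-shifting-cultivation (*kaingin*) fallow forests against
old-growth controls. The sampling design is 25 sites — four fallow-age
categories (SA0–5, SA6–10, SA11–20, SA21–30 years since abandonment)
plus old-growth (OG), five replicate sites each — with four parallel
50 m × 5 m transects per site (0.1 ha sampled) and one 1 m × 1 m
destructive quadrat per transect for litter and undergrowth.

Five tidy CSV tables carry the census: sites (covariates and design
geometry), live stems (≥ 5 cm dbh, with height, wood density, guild,
origin), other living stems (tree ferns and Abaca, diameter only),
dead-wood pieces (diameter, in-transect length, standing/downed, decay
class) and quadrat samples (dry mass, carbon fraction). Units are
fixed at the schema: diameters cm, heights/lengths m, density g cm⁻³,
slope degrees, quadrat mass grams. Validation enforces the census
threshold (dbh ≥ 5 cm), enum domains, referential integrity of
`site_id`, and the OG ⇔ no-fallow-age rule; `read ∘ write` is the
identity on validated inventories (floats are written with shortest
round-trip formatting and parsed with round-trip precision).

## Biomass and carbon

Component dry masses come from closed-form allometries
(`allometry.py`): the Chave et al. (2014) pantropical model
`AGB = 0.0673 (ρD²H)^0.976` (kg) for trees and palms; power laws
`a·D^b` for tree ferns (native output grams, converted to kg) and
Abaca; and a solid-cylinder volume `π(D/100)²L/4` times a decay-class
density for dead wood. All coefficients live in
`AllometryCoefficients`/`DecayDensityTable` and are YAML-overridable,
so every transcribed constant is auditable without code changes. The
fern and Abaca defaults (31.6·D^2.5 g; 0.08·D^1.9 kg) are
package-chosen plausible magnitudes for the cited model families;
because other living biomass is < 1.5% of any category total, results
are insensitive to them, but users with the original coefficients
should set them in the config. The cylinder form deliberately uses the
piece-level measured length (no taper or line-intersect correction)
and a single diameter per piece, matching how the pieces are recorded.

Wood density resolves species → genus mean → global default
(0.57 g cm⁻³, configurable). Carbon fractions default to 0.50 for
trees, ferns, dead wood, litter and undergrowth and 0.473 for Abaca;
per-quadrat measured fractions override the defaults when present.

Per-site pools (Mg C ha⁻¹) divide summed component carbon by the
slope-corrected horizontal area `n·L·W·cos(slope)/10⁴`. Litter and
undergrowth are scaled on the quadrat area (number of quadrats × 1 m²,
same cos correction — the consistent choice, since those components
are sampled only in quadrats). Degenerate inputs are defined, not
errors: an empty component contributes 0; a slope ≥ 90° is rejected.
`AGTBC` is the sum of the five pools and every breakdown (guild,
origin, dbh class [5,10,30,50) cm, height class [0,10,30,50) m, kind,
stand form, decay class) sums to its parent pool to 1e−9 relative;
these conservation identities are asserted over all synthetic sites.

## Recovery

`R = 100 · X_fallow / mean(X_control)` per pool, with undergrowth and
litter combined (ULBC) for the modelling responses and OLBC kept
separate in descriptive summaries. R requires a positive control mean
and may exceed 100 (new-fallow dead wood typically does). Category
summaries report mean ± SD and the median. When only category-mean
summary data exist (the bundled published table), recovery is computed
from category means; with site-level pools it is computed per site —
both paths are exposed because the mixed models need site-level
responses while the published worked examples are category-level.

## Inference

One-way ANOVA with Tukey's HSD (studentized-range adjusted p-values)
compares pools across the five categories; on the full design the
degrees of freedom are (4, 20). The identical-groups edge case is
defined as F = 0, p = 1.

The mixed models regress per-site recovery on subsets of five
standardized covariates — fallow age (FA, yr), distance to the nearest
control forest (DIS, m), slope (SL, °), patch size (PS, ha) and soil
organic carbon (SOC, %) — with a random intercept per fallow category.
With one response value per site, a site-within-category random effect
is indistinguishable from the residual, so the site level is absorbed
into the residual; this is the identifiable reduction of a
sites-nested-in-categories design and is the package's documented
choice. Fits use maximum likelihood, not REML, because REML
likelihoods are not comparable across different fixed structures. The
parameter count k is fixed effects (incl. intercept) + 2 variance
components; AICc uses n = number of fallow sites (20). When the
random-intercept variance estimate hits the 0 boundary (common at
n = 20) the boundary ML fit — OLS with the variance pinned at 0 — is
retained with a warning rather than discarded. All 2⁵ = 32 subsets are
fitted; Akaike weights are normalised over every fitted model; ties in
AICc are broken by fewer parameters, then lexicographic subset order;
ΔAICc ≤ 4 flags the equivalence set. Variable importance sums weights
over models containing a variable, reported for the full set and the
equivalence set (the published table's weights appear renormalised
within the displayed subset, so both scopes are emitted). A greedy
pairwise-|r| screen (threshold 0.7, priority to the five canonical
covariates) excludes collinear covariates; on the synthetic covariates
it excludes elevation and LAI by construction.

## Synthetic generator

`generate_inventory` draws a full 25-site inventory from one integer
seed (same seed → byte-identical CSVs). Stand structure per category:
truncated-Weibull dbh (shape 1.1–1.6, scale 14–16.5 cm), height
`a·D^b` with lognormal scatter (σ = 0.15), species sampled from a
small Philippine lowland list (Parashorea malaanonan weighted to rank
first in living woody carbon), guild/origin mixtures and dead-wood
decay/stand-form mixtures set from the published category composition
(new fallows: predominantly fresh and standing; old growth:
predominantly highly decomposed and downed). The per-category stem
density, dbh scale, dead-wood load and quadrat masses were calibrated
once against the published category-mean pools — across seeds the
generator lands within a few percent of, e.g., 316.96 Mg C ha⁻¹
old-growth LWBC and 126.65 Mg C ha⁻¹ new-fallow CDWBC — and then
frozen. Covariates: slope U(5°, 35°), patch size lognormal (median
4 ha, ≥ 1 ha), distance U(100, 3000) m, SOC U(2.5, 8)%, with
elevation = 150 + 9·slope + N(0, 35) and LAI = 1.2 + 0.13·FA +
N(0, 0.35) supplying detectable collinearity.

The generator emulates pool magnitudes and the design, **not** real
stand structure: no spatial stem mapping, no successional dynamics, no
species–guild coupling, independent draws across sites. Passing tests
therefore demonstrate correctness of the accounting and inference
machinery under the study's design and magnitudes, not ecological
realism of any particular stand.

`generate_recovery_scenario` additionally plants a known linear signal:
old-growth sites define the control mean, then each fallow site's
living woody stock is built by drawing stems until the target
`intercept + Σβ·z(cov) + noise` recovery is reached, solving the last
stem's height so the target is hit exactly. It returns the ground
truth, enabling parameter-recovery tests: with PS and SOC effects
(β = 10 and 8 recovery points per SD, noise SD 3) those two variables
attain the top-2 Akaike importance in ≥ 90% of 50 seeded replicates.

## Problem sizes and numerical choices

Default test and example runs use the study-scale design (25 sites,
~2000 stems, ~700 dead-wood pieces); replicate-based checks use 20–50
seeds/replicates. Conservation tolerances are 1e−9 relative; equation
oracles are checked to 1e−9 relative on ≥ 100 random inputs; published
worked examples are asserted to ±0.01 (one unit of the printed
precision — one published recovery, 37.86%, is the published rounding
of a value that computes to 37.866 from the printed means).

## Known limitations

* No uncertainty propagation through allometric model error.
* Fern/Abaca coefficients are configurable placeholders of the right
  magnitude (see above).
* Site-level random effects are not separately identifiable (one
  observation per site); the category-level random intercept is the
  supported structure.
* Belowground biomass and soil carbon stocks are out of scope (SOC
  enters only as a covariate).
* Whether quadrat areas should be slope-corrected is ambiguous in the
  field protocol; they are corrected here for consistency with the
  transect areas.
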