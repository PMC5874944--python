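# Methods

`gridtr` models the radiobiology of grid therapy (spatially fractionated
radiotherapy, SFRT): a perforated block converts an open megavoltage field
into a lattice of pencil beams, deliberately underdosing the tissue between
holes. The package answers two questions: *for which tumours* does this
trade-off pay off, and *which block geometry* maximises the payoff.

## Single-hole geometry and the dose profile

The hexagonal hole lattice is reduced to one representative hole: the
tissue belonging to a hole is the disc of radius `r_max = spacing / 2`
(the circular approximation to the hexagonal unit cell; the hexagon/circle
coverage deficit is ignored). All dosimetry enters through a radial dose
profile `D(r)` on `[0, r_max]`, in mm and Gy.

Measured or simulated profiles can be supplied as two-column CSV
(`r_mm,dose_Gy`). The built-in surrogate is a three-parameter shape:

- a **valley floor** `v` (default 0.22): the fraction of the peak dose
  reaching the mid-septum point, representing block transmission plus
  phantom scatter. The default reproduces the ~22% valley-to-peak ratio
  reported for a 1.0 cm hole / 1.8 cm pitch block at 5 cm depth;
- an **error-function penumbra** of Gaussian width `penumbra_sigma`
  (default 1.5 mm, a typical 6 MV penumbra scale) centred on the hole edge;
- the penumbra is **mirrored about `r_max`**: the valley point receives the
  tails of both adjacent holes. This term is what penalises thin septa —
  with a 1.5 cm hole on a 1.8 cm pitch the two penumbrae overlap and the
  valley fills in to ~0.47 of the peak. Without it, EUD-matched TR is
  monotone in hole diameter and no interior design optimum exists.

The profile is normalised to its central value, so `peak_dose` is the dose
on the hole axis exactly. Consequences worth knowing: the realised
valley-to-peak of the canonical profile is 0.226 rather than 0.220 (the
mirror tail raises the valley by ~0.6 percentage points), and for holes
much smaller than the penumbra the central region is a rounded peak rather
than a flat plateau — both physically expected. The valley floor and
penumbra width are held constant across geometries in design sweeps; an
alternative in which the valley floor scales with the lattice open-area
fraction was evaluated and rejected (it flattens neither sweep and destroys
the diameter optimum).

Depth dependence is not modelled: the profile represents one depth (the
published valley ratio refers to 5 cm) and all results are single-depth,
single-fraction.

## Survival models

**LQ.** `SF(D) = exp(-αD - βD²)`. Parameters derive from two tabulated
clinical quantities, SF2 (surviving fraction at 2 Gy) and the α/β ratio:

    α = −ln(SF2) / (2 + 4/(α/β)),   β = α / (α/β).

Tumours use α/β = 10 Gy, normal tissue SF2 = 0.4 with α/β = 2.5 Gy.
Radiosensitivity classes: radiosensitive SF2 < 0.4, semisensitive = 0.4,
radioresistant > 0.4.

**Hug–Kellerer.** `SF(D) = exp(−k₁D + k₂(1 − e^(−k₃D)))` tends to a pure
exponential at high dose, where the LQ quadratic is widely held to
over-predict kill. Two parameter relations tie it to the LQ pair:

    α = k₁ − k₂k₃,   β = k₂k₃²(ln2 − ½)/(ln2)².

These fix two of three degrees of freedom; the β relation is algebraically
equivalent to demanding *exact* LQ/H-K agreement at the dose `D₀ = ln2/k₃`,
so k₃ chooses where the curves cross. Closing the system by additionally
matching SF2 exactly at 2 Gy forces `k₃ = ln2/2` for every cell line; that
curve departs from LQ by ~8% already at 4 Gy and by a factor ~3 at 6 Gy for
normal tissue, which makes the H-K therapeutic ratios diverge ~30% from LQ
— useless as a cross-check and inconsistent with the near-identity of the
two models' TRs that the H-K model is meant to demonstrate. `gridtr`
therefore keeps the two relations exact and chooses k₃ by least squares of
log-survival against the LQ curve over 0–10 Gy, the range where the LQ
model is clinically trusted; beyond it the H-K form extrapolates with a
shallower curve (`SF_HK ≥ SF_LQ` at 20 Gy for every line). The objective
factors as `β²·f(k₃·D)`, so the optimum k₃ (≈ 0.0816 Gy⁻¹) is shared by all
cell lines; the fit is a deterministic bounded 1-D minimisation, verified
in tests against a dense grid-search oracle. The price of this closure is
that `SF_HK(2 Gy)` matches SF2 only to ~5% (worst at high β) — acceptable
because every H-K quantity of interest here is a ratio in which the
deviation largely cancels.

## Grid survival, EUD, therapeutic ratio

The disc is tiled with concentric rings of 0.1 mm thickness (spec: halving
to 0.05 mm changes grid SF by < 0.1%). Ring `i` carries relative cell
number `V_i = (r_{i+1}² − r_i²)/r_max²` (ΣV_i = 1 exactly) and receives the
profile dose at its mid-radius (second-order accurate). The grid-field
surviving fraction is `SF = Σ V_i · SF_model(D_i)`; an independent
trapezoid-rule integration of `(2/r_max²)∫ r·SF(D(r)) dr` agrees within
0.5% and serves as the test oracle.

The **equivalent uniform dose** is the uniform dose with the same tumour
survival as the grid field: for LQ the positive root of
`βE² + αE + ln SF = 0` (unique since α, β > 0; the negative root is
discarded), for H-K a bisection of the monotone survival curve. By
construction `min D(r) ≤ EUD ≤ max D(r)`.

The **therapeutic ratio** compares normal-tissue survival under the grid
field against a uniform field at iso-tumour-effect:

    TR = SF_normal(grid) / SF_normal(EUD),

with both tissues evaluated under the same survival model. TR = 1 exactly
for a flat profile (any cell line, both models — machine-precision test).
"Dose" labels (2/10/15/20 Gy) always denote the profile's peak dose.

## Design sweeps

Geometries are compared at matched tumour EUD: for each candidate geometry
the peak dose is rescaled (bisection; EUD is strictly increasing in peak
dose) until its EUD equals that of the reference operating point — the
canonical 1.0 cm / 1.8 cm block at a 15 Gy peak, the widely used
single-fraction grid prescription. Sweep TRs default to the radioresistant
class (the intended clinical target of grid therapy). Optima are reported
as the set of geometries within 1% of the maximum TR, avoiding knife-edge
ties from discretisation. Default grids: diameters
{0.5, 0.75, 1.0, 1.25, 1.5} cm at 1.8 cm pitch; spacings
{1.6, 1.8, 2.0, 2.2} cm at 1.25 cm diameter.

## Clinical correlation

Two bundled literature tables — study-level total response of grid-treated
tumours by histology, and published SF2 by histology — are joined on
histology ("SCC of H&N" → SCC). Responses quoted as lower bounds are stored
with a `>=` qualifier; a blank response (parotid) and a histology without
published SF2 (maxillary sinus) are kept as records but excluded from fits.
`fit_linear_response` is an ordinary least-squares line of response against
either SF2 or the model TR (computed at the 15 Gy reference peak, α/β = 10);
a positive slope with either predictor is the model's clinical validation.

## Fidelity limits of the surrogate profile

What passing tests show is that the *pipeline* (ring decomposition, EUD,
TR, H-K tie, EUD-matched sweeps) reproduces the published analysis given a
faithful profile; the surrogate itself has known limits:

- The erf penumbra assigns more disc area to intermediate doses than the
  original Monte-Carlo profile appears to. TRs for low-β, high-SF2 tumours
  are the most sensitive to that region: the radioresistant class computes
  1.50/2.02/2.63 at 10/15/20 Gy against the published 1.34/1.76/2.28
  (outside the ±0.15 band), and TR(SF2 = 0.55, 15 Gy) computes 2.44 vs the
  published 2.03. Radiosensitive and semisensitive TRs, the EUD anchor
  (4.74 Gy vs 4.41 ± 0.5) and the LQ/H-K agreement (≤ 0.5% at 20 Gy vs the
  published ≤ 4%) are reproduced.
- EUD-matched TR across spacings varies by ~21% of the mean on the
  surrogate, versus the published ±4% stability; reproducing that flatness
  evidently needs the real per-geometry valley behaviour. The *location*
  of the spacing optimum (1.8 cm) and the diameter optimum
  ({1.0, 1.25} cm, ~19% above the other diameters) are reproduced.

Numerical conventions: radii in mm, doses in Gy, profiles on `[0, r_max]`
with `r_max = spacing/2` exactly; all solvers are deterministic (no RNG
anywhere in the library); solver tolerances are 1e-12 (survival/EUD
inversions) and 1e-9 Gy-scale (EUD matching in sweeps).
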