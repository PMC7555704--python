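# Methods

This note records the models implemented in `pyrscat`, the assumptions
behind them, the parameter defaults and the numerical choices, in the
package's own words. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. The cross-section compilation

The package ships two CSV tables transcribed cell-for-cell from the
compiled recommendation for electron–pyridine scattering:

* `table1_recommended.csv` — integral cross sections for six channels on a
  common energy grid from 0.11 to 100 eV (units 10⁻²⁰ m²). The elastic
  column joins an R-matrix calculation below 10 eV to an IAM-SCAR
  calculation above; attachment comes from R-matrix shape resonances;
  rotational excitation from a dipole-Born calculation (2.2 D permanent
  dipole); ionization from averaged beam measurements; electronic
  excitation from the IAM-SCAR ionization/electronic ratio applied to the
  total inelastic cross section; vibrational excitation is the closure
  remainder of the reference TCS.
* `table2_smc.csv` — an alternative elastic channel from a
  Schwinger-multichannel (SMC, pseudopotential, SEP-level) calculation on a
  dense 0.1–20 eV grid, used for sensitivity studies. Above 20 eV the
  recommended elastic values are appended so the variant spans the full
  range.

Encoding decisions:

* Cells printed as **"<0.1"** (channel onsets) are upper bounds. They are
  kept verbatim in the CSV and decoded on load to the interval midpoint
  0.05 with a per-point bound flag, preserving both channel-onset
  continuity and the recoverability of the printed bound.
  `CrossSectionSet.serialize_table()` re-emits the table verbatim.
* **Blank cells** are absent grid points, not zeros. Below a threshold
  channel's first tabulated energy (and above the last one — e.g.
  vibrational above 3.2 eV, attachment above 1.2 eV) queries return a zero
  cross section: "no data → no contribution". This is a documented reading
  of the compilation, which does not state whether those channels are
  closed or merged into other columns at such energies.
* The SMC table's **spike at 0.9 eV** (81.96 between neighbours at 32.47
  and 34.43) is retained verbatim for fidelity to the source.

Interpolation is linear in (ln E, ln σ) by default — the tabulated values
span four orders of magnitude and most channels are smooth power-law-like
segments — except inside windows that contain densely tabulated sharp
structure, where it is linear-linear so peak shapes are not distorted:
the two attachment resonances (0.71–0.935 and 1.01–1.2 eV) and the SMC
0.8–1.0 eV window. Grid energies return the stored value exactly. There is
no extrapolation: the recommended variant answers queries on
[0.11, 100] eV (the first printed energy is 0.11 eV), the SMC variant on
[0.1, 100] eV; outside, a range error is raised. Sub-0.1 eV electrons are
the transport cull rule's problem, not the interpolator's.

Gas conditions convert to number density as n = P/(k_B·T_eff) with the
pressure in Pa (1 mTorr = 0.1333224 Pa) and T_eff = √(T_C·T_m), the
geometric mean of the scattering-chamber and capacitance-gauge
temperatures (thermal-transpiration correction). The mean free path is
λ = 1/(nσ); cross sections are stored in 10⁻²⁰ m² everywhere, converted to
SI only here.

## 2. Missing-angle corrections and closure

A transmission experiment counts electrons scattered into the detector's
forward acceptance cone as unscattered, so the measured TCS is low by
Δσ = 2π ∫₀^θacc (dσ/dΩ)(E,θ) sinθ dθ for each forward-peaked channel.
Two acceptance models are provided:

* **fixed_angle** — a geometric aperture (default 5°), as in a linear
  transmission beam;
* **energy_resolution_linked** — for magnetically confined apparatus,
  where a scattering event registers only once the axial-energy decrement
  E(1−cos²θ) exceeds the energy resolution ΔE_res. The acceptance
  half-angle is therefore θ_acc = arccos(√(1−ΔE_res/E)), the pitch angle
  whose axial-energy loss equals the resolution; at E ≤ ΔE_res every angle
  is unresolved and the sentinel π/2 is returned. This formula is the
  package's reading of "acceptance linked to energy resolution" and is
  isolated behind `AcceptanceModel` so alternatives can be plugged in.

The correction integral uses adaptive Gauss–Kronrod quadrature
(`scipy.integrate.quad`, relative tolerance 10⁻⁸) with the domain split at
θ_acc/10 so the near-forward peak of dipole-like integrands is resolved.
Closed-form checks (isotropic and cos²θ shapes) and the full-sphere limit
(Δσ(π) = ICS) are part of the test suite.

Closure rules: `close_vibrational` attributes the remainder of the
reference TCS (which excludes rotational excitation, by the convention of
the corrected transmission measurements) over elastic + electronic +
ionization + attachment to vibrational excitation; a negative remainder is
an inconsistency diagnostic, clipped to zero and logged, never
propagated — consistent with the blank vibrational cells of the table.
Attachment is included in the closure budget (it is a real scattering
channel); the compilation does not state this either way, so it is a
documented package choice. `split_inelastic` divides a total inelastic
cross section as electronic = total/(1+r), ionization = total·r/(1+r); the
energy dependence of the IAM-SCAR ratio r is not printed, so r is an input
rather than a constant.

## 3. Angular models

**Elastic.** The compilation's ab initio elastic DCS curves are not
tabulated, so the default shape is screened-Rutherford,

    dσ/dΩ = C(E) / (1 + 2η(E) − cosθ)²,   η(E) = η₀/E,

with C(E) fixed analytically by the normalization
2π∫(dσ/dΩ)sinθ dθ = σ_el(E) (the full-sphere integral of the shape is
π/(η(η+1))). The default η₀ = 1 (η in eV/E) makes the 10 eV shape strongly
forward-peaked (forward/backward ratio (1+1/η)² ≈ 121) and progressively
flatter toward low energy, mimicking the qualitative behaviour of the
ab initio curves. Users with digitized DCS data can substitute a
`TabulatedDCS` (bilinear in (E, θ), per-energy renormalized to the ICS).

**Rotational.** The dipole-Born shape is 1/K², with momentum transfer
K² = k² + k′² − 2kk′cosθ and nonrelativistic momenta for the mean
rotational excitation energy ε_rot = 0.00109 eV. Its full-sphere integral
has the closed form (2π/kk′)·ln((k+k′)/(k−k′)), used for exact
normalization. The magnitude is pinned to the tabulated rotational ICS
rather than to an ab initio Born integral: this preserves both printed
facts — an essentially energy-independent shape and a ~1/E magnitude
fall-off — without inventing constants. The residual deviation from exact
1/E scaling at fixed angle (up to ~2% across the range, measured in the
test suite) is inherited from the tabulated ICS column itself.

**Inelastic.** The semi-empirical double-differential shape raises the
elastic DCS to a fractional power of the relative energy transfer:

    eq1:  (dσ/dΩ)ₑₗ^(1−ΔE/E)          (original form)
    eq2:  (dσ/dΩ)ₑₗ^((1−ΔE/E)^k),  k = 1.3   (improved form)

This power-law reading of the compact printed expression is a deliberate
interpretation, adopted because it is the only one satisfying both
constraints the source states: the improved form reproduces the original
at small ΔE (exponents coincide as ΔE/E → 0) and is *flatter* at large ΔE
when k > 1 ((1−x)^k < 1−x for 0 < x < 1, and a smaller exponent on a
peaked shape reduces its contrast). A multiplicative reading
(elastic DCS × (1−ΔE/E)^k) is rejected: it would rescale but never
flatten the angular distribution, contradicting the observed large-angle
flattening of the measured DDCS.

On the quantitative eq1/eq2 agreement at small loss: for any
forward-peaked elastic DCS the *pointwise* ratio of the two shapes spans
dcs^(Δp) with Δp = (1−x)−(1−x)^k ≈ 0.015 at x = 0.05, i.e. ~10% over a
four-decade dynamic range — a pointwise sub-1% match is mathematically
unattainable there. The agreement that holds, and that the package tests,
is distributional: the Kolmogorov–Smirnov distance between the two
normalized angular distributions is below 1% for ΔE/E ≤ 0.05 at 15 eV
(the regime where such small relative losses actually occur in transport,
i.e. vibrational excitation) and converges to zero as ΔE/E → 0 at all
energies. The distributions are what the transport engine samples, so this
is the operationally relevant statement.

**Sampling.** All angular draws are inverse-CDF samples of
pdf(θ)·sinθ on a 1024-point uniform θ grid with trapezoidal accumulation;
azimuth is uniform on [0, 2π). Sampling is deterministic under a seeded
`numpy` Generator. The transport engine memoizes CDFs keyed exactly by
(channel, energy, exponent) — an exact key, so a cache hit can never
change a result and runs are bit-reproducible regardless of cache history.

## 4. Energy-loss models

Per-channel samplers return (deposited, secondary) energies with the exact
per-event budget E_in = E_out + deposited + secondary:

* **rotational** — fixed 0.00109 eV (300 K average), no secondary;
* **elastic** — two-body recoil ΔE = [4mₑM/(mₑ+M)²]·E·(1−cosθ)/2 with
  M = 79 amu (≈2.8 meV for 100 eV backscatter);
* **vibrational** — discrete mixture at {0.1, 0.2, 0.4} eV with weights
  {0.5, 0.3, 0.2}, truncated and renormalized above the incident energy;
* **electronic** — Gaussian mixture with means {4.8, 7.0} eV, σ = 0.5 eV,
  sampled exactly from the (0, E)-truncated mixture by inverse CDF, so the
  model stays defined just above the 3.5 eV channel onset;
* **ionization** — the primary loses B + W: the binding energy B
  (default 9.6 eV) is deposited and the secondary carries W, drawn from a
  Lorentzian-tailed density ∝ 1/(W² + w²) (w = 10 eV) truncated to
  [0, (E−B)/2] so the secondary is by convention the slower outgoing
  electron. The bookkeeping convention (deposited = B, secondary = W,
  primary loss = B + W) is chosen so the per-event budget closes without
  double-counting the secondary's energy;
* **attachment** — the projectile is absorbed and its entire kinetic
  energy deposited.

The vibrational and electronic mixtures and the ionization secondary
spectrum are parametric **stand-ins**: the measured angle-averaged
energy-loss spectra they emulate are published only as figures. The
faithful path is the spectrum reader, which splits a two-column
(loss, intensity) CSV at the channel onsets (3.5 eV for electronic,
B for ionization — both taken from the integral-table onsets, both
configurable) into normalized per-band samplers. B = 9.6 eV itself is a
package choice placed inside the onset bracket of the ionization column
(upper bound printed at 10 eV, first value at 12 eV), not a printed
number. The Lorentzian tail of the secondary spectrum is likewise a
package decision flagged for sensitivity analysis; nothing in the source
states the sampled form.

Electrons below **0.1 eV** are culled and their residual energy tallied as
locally deposited.

## 5. Transport engine

Event-by-event Monte Carlo: free path s = −λ ln u with λ from the total
cross section at the electron's current energy; channel choice by relative
integral cross sections; polar angle from the channel's angular model
(inelastic channels use the eq2 exponent for the sampled loss); azimuth
uniform; direction update by explicit 3-D rotation with no small-angle
approximation; energy update per the loss model. Secondaries are pushed on
a LIFO stack and transported with the same physics, with a generation cap
of 3 to bound runtime (energy of dropped secondaries stays in the ledger
as `secondary_untracked`). Over the sliver between the cull threshold
(0.1 eV) and the first tabulated energy (0.11 eV in the recommended
variant), cross-section lookups clamp to the grid edge.

Geometry is a cell of length L along z. Forward exits (z ≥ L) are the
transmitted population. Backscattered electrons reaching the source plane
are **lost** by default (removed and logged); a **reflected** policy
(specular return at z = 0, free path redrawn — exact for the memoryless
exponential) is available, since the real apparatus' behaviour at the
source plane is not specified in the compilation. L defaults: 0.05 m for
the linear spectrometer preset (`GasConditions` default), 0.14 m as the
package's configurable choice for the confined cell, whose length is not
printed.

The beam is Gaussian with default FWHM 0.45 eV (midpoint of the stated
0.4–0.5 eV natural spread), truncated below the cull energy.

Under magnetic confinement (~0.1 T in the modelled apparatus) the
gyro-radius is microns, so transverse displacement is frozen to zero and
scattering manifests purely as axial-energy loss E_∥ = E·d_z². The RPA
transmission curve counts forward exits with E_∥ ≥ eV_R per incident
electron; by default only primaries are counted, keeping the
normalization ≤ 1. Per-run energy accounting
(injected = exited + deposited + culled + untracked) closes to float
accumulation precision (tested at 10⁻¹² relative), and identical seeds
give bit-identical event logs.

The virtual attenuation measurement reports
σ_eff = ln(I₀/I)/(nL), with I counted under perfect discrimination (only
never-collided primaries), an angular acceptance cone, or an axial-energy
window; finite acceptance reproduces the missing-angle deficit of real
transmission measurements. The thin-target regime (nσL ≲ 0.5) is the
intended operating point.

Imperfect magnetic confinement at high beam energy (a suspected systematic
in the measured 90 eV transmission) is **not** modelled; the confinement
flag is all-or-nothing in this version.

## 6. Synthetic DDCS and exponent fitting

The generator emulates reaction-microscope relative DDCS: curves at fixed
energy losses (default grid 1°–180°) equal to the eq2 shape evaluated on
the default elastic model, times multiplicative lognormal noise of a given
fraction (default 5%), with the error column set to fraction × value. It
emulates the *shape* statistics only — no coincidence kinematics, detector
acceptance, ion time-of-flight or parent/fragment branching, and no
absolute scale (the experimental absolute normalization carries ~20%
uncertainty and is deliberately a free per-curve parameter here).

The fitter solves, by weighted least squares in log space
(`scipy.optimize.least_squares`, tolerances 10⁻¹²),

    ln DDCS_j(θ) = ln s_j + (1−ΔE_j/E)^k · ln (dσ/dΩ)ₑₗ(E,θ)

jointly for k and the per-curve scales s_j; weights are the relative
errors (= absolute errors of the log). Angles below 1° are excluded
(dipole-like forward divergence; measured grids start above 0°). The
standard error of k comes from the Gauss–Newton covariance (JᵀJ)⁻¹. The
design matrix has full rank whenever two distinct losses and three angles
are present; degenerate inputs raise. Recovery calibration (noiseless
inversion to 10⁻⁶; mean over 200 noisy replicates within 0.05 of the
generating k = 1.3) is computed by the test suite and
`scripts/acceptance.py`.

## 7. Problem sizes and limitations

Test-suite simulation sizes are chosen to make each statistical assertion
sharp at its stated tolerance while keeping the default run quick:
10⁵ electrons per point for the Beer–Lambert ladder and the vacuum RPA
check (binomial/quantile errors ≲ 0.2%), 10⁴ for the rotational-loss
audit, 2×10⁴–4×10⁴ for attenuation cross-checks, and a few hundred for
full-physics bookkeeping runs.

Known limitations, beyond those noted above: no space charge, field maps,
detector efficiency or transverse beam optics; no fragmentation-channel
resolution in the energy bookkeeping; no uncertainty propagation beyond
the compiled 10–20% bands (recorded as provenance metadata, not sampled);
the packaged tables are consumed as printed — the underlying R-matrix,
SMC and IAM-SCAR calculations are outside the package's scope. Passing
tests show the engine is faithful to its inputs and self-consistent; they
do not show that the parametric stand-in spectra match pyridine's real
energy-loss spectra.
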