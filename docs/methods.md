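# Methods

## The scientific setting

NMDA-receptor ligand-binding domains (LBDs) are bilobed "clamshell" modules
whose opening/closing motion is summarized by a single order parameter
*d*: the distance between two marker C&alpha; atoms, one per lobe (residues
507/701 in GluN1, 503/701 in GluN2B), in nm. Closed-clamshell conformations
sit near 3.7 nm, open ones near 4.7 nm. N-linked glycans (Man5) tethered to
lobe S1 can transiently contact lobe S2; the contact geometry is summarized
by *d*<sub>g-ol</sub>, the minimum heavy-atom distance between the glycan
and a residue range on the opposite lobe (710&ndash;723 for the GluN1-N440
glycan). The package implements the statistics used to ask whether such
glycans shift the open/closed equilibrium: MSM-reweighted densities of *d*,
per-bin percentile-bootstrap comparisons of conformational ensembles,
implied timescales of the opening/closing transition over an estimator
grid, glycan contact profiles, and Hill-fit EC50 comparisons between
wild-type and glycosylation-deficient receptors.

Since no trajectory data are deposited for this system, every input is
synthetic, generated by `glycoclam.synthetic` under known ground truth.
Passing tests therefore demonstrate estimator correctness and calibration
on data with the stated statistical structure — not anything about real MD
trajectories.

## The two-state generator

The hidden dynamics of *d* are a continuous-time two-state Markov process
(open &harr; closed) with rates `rate_close` (open&rarr;closed) and
`rate_open` (closed&rarr;open), both in 1/ns. The process is sampled
*exactly* at the frame spacing `dt` through its matrix exponential — not an
Euler step — so two quantities are known in closed form and serve as
oracles everywhere:

* slowest relaxation time &tau; = 1/(rate_close + rate_open),
* equilibrium closed fraction &pi;<sub>c</sub> = rate_close/(rate_close + rate_open).

Emissions are state-dependent Gaussians. Defaults (the study conditions):
basin means 3.7/4.7 nm, emission sd 0.15 nm, dt = 0.2 ns, 262 trajectories
of 2000 frames, rates 0.002/0.001 ns&sup1; (&tau; = 333 ns,
&pi;<sub>c</sub> = 2/3). The 0.15 nm width and 0.1 nm analysis bins put the
enriched/depleted ranges on the same lattice as the reference analysis
(3.6&ndash;3.8 nm closed-enriched, 4.6&ndash;4.8 nm open-depleted).
Trajectories are initialized from equilibrium; real MD ensembles started
from a fixed library of geometries would carry an initial-state bias that
the reweighting machinery is designed to remove, and that bias is *not*
emulated here.

The toy glycoprotein converts a *d* series into a multi-model PDB: two
pseudo-C&alpha; arms hinged at the origin (arm length 4 nm; the hinge angle
is the monotone image of *d*), one carrying marker residue 507, the other
marker 701 plus the 710&ndash;723 range, and an 11-atom pseudo-glycan chain
tethered to lobe A. In closed frames (d &le; 4.2 nm) the glycan is rotated
toward the opposite lobe with probability `contact_when_closed`, ending
0.35 nm from it; otherwise it points away (&gt; 2 nm clearance). The joint
event (d &gt; 5.2 nm and d<sub>g-ol</sub> &lt; 0.5 nm) is therefore
impossible by construction, which is the structural-coupling property the
joint histogram must reproduce exactly. Only distance statistics are
consumed downstream, so no attempt is made at realistic glycan
stereochemistry.

Dose-response curves are Hill curves I(c) = I<sub>max</sub>
c<sup>h</sup>/(EC50<sup>h</sup> + c<sup>h</sup>) on the 0.1&ndash;100 uM
half-log ladder with multiplicative Gaussian noise (`noise_sd`, default 3%
of the signal). Generating EC50 values are the published wild-type
(2.28 uM) and N440Q-mutant (3.43 uM) numbers; h = 1.4.

## MSM estimation

Discretization is k-means on the 1-D *d* series (the featurization is a
configuration knob; 1-D is the default because the order parameter is the
quantity of interest), with a fixed-seed k-means++ initialisation and
nearest-centre assignment breaking ties toward the lower centre index.
Transition counting is sliding-window at the chosen lag; trajectories
shorter than the lag are skipped, never padded. Counts are trimmed to the
strongly connected component with the largest total count (no
pseudocounts). The transition matrix is the maximum-likelihood estimate
under detailed balance (default), computed by the standard fixed-point
iteration on the symmetric count variables, converged when the maximum
relative change of the state weights falls below 1e-10; the non-reversible
row-normalized estimate is also available since the reference analysis does
not state reversibility. Implied timescales are t<sub>i</sub> =
&minus;&tau;<sub>lag</sub>/ln &lambda;<sub>i</sub> for eigenvalues in
(0, 1); eigenvalues &ge; 1 report as infinite and &le; 0 as undefined
(NaN). The estimator grid mirrors the reference table: k &isin; {99, 6},
lag &isin; {256, 128} ns, plus tICA.

tICA accumulates mean-free instantaneous and symmetrized time-lagged
covariances per trajectory (no cross-trajectory pairs), solves the
generalized eigenproblem with a 1e-10 ridge on the instantaneous
covariance, and converts eigenvalues to timescales as above. On a 1-D
series the leading eigenvalue is exactly the symmetrized lag
autocorrelation, which is the oracle used in tests. With state-dependent
emission noise the observed series is not exactly Markov and tICA
timescales are attenuated by the noise-to-signal ratio; the
estimator-consistency experiment therefore uses a small emission width
(0.02 nm) so all four estimators target the identical relaxation time.

Sampling adequacy matters more than estimator choice at this problem size.
At the calibrated study scale (262 trajectories &times; 400 ns, &tau; =
520 ns, lag 256 ns) only on the order of 10&sup2; open&harr;closed
transitions occur in the whole ensemble, giving the slowest-timescale
estimate a sampling sd of roughly 12%; recovery experiments at this scale
are expected to scatter accordingly.

## Densities, reweighting and the bootstrap

Densities of *d* are histograms on a uniform 0.1 nm lattice, normalized to
unit integral. MSM reweighting assigns each frame the weight
&pi;(state)/(frames observed in that state) so that each state's total
weight equals its stationary probability; frames in trimmed states are
dropped and logged. Ensembles are compared bin-by-bin with a percentile
bootstrap whose resampling unit is the whole trajectory — frames within a
trajectory are autocorrelated, so frame-level resampling would understate
uncertainty. Each replicate redraws trajectories with replacement within
each ensemble independently; the per-bin difference CI is the empirical
&alpha;/2 and 1&minus;&alpha;/2 quantile at level 0.95 (default, 1000
replicates), and a bin is significant when its CI excludes zero. No
multiple-testing correction is applied across bins (flagged in the output
metadata). When comparing reweighted densities the default reuses the
per-frame weights across replicates ("fixed-weights"); re-estimating the
MSM per replicate is possible but expensive and not the default. Coverage
of the interval is validated against the analytic bin density of the
generator (a two-Gaussian mixture weighted by the equilibrium state
populations), using 500 independent ensembles of 50 trajectories &times;
1000 frames: with trajectory-level resampling of 50 heavily autocorrelated
trajectories the empirical coverage sits at ~93%, within the binomial band
around the nominal 95%.

## Dose-response analysis

Curves are normalized to the observed maximum (fitting I<sub>max</sub>
instead is an option), fitted per curve by unweighted least squares with
initialization EC50 = geometric mean of the concentrations, h = 1,
I<sub>max</sub> = max response, and h bounded to (0.2, 5). Groups are
compared with an equal-variance two-sample Student's t-test on the
per-curve EC50 values (a log-EC50 option exists); the headline quantity is
the percent change of the mutant group mean relative to wild-type. Fitting
per curve and then testing group means (rather than fitting the averaged
curve) is the default because it yields a per-group dispersion for the
t-test.

## Numerical and design notes

* Structures are stored in &Aring;ngstr&ouml;m (PDB native); all distances
  are converted to nm at the order-parameter boundary.
* Heavy atom means element not in {H, D}; elements are inferred from the
  atom-name column when the element field is blank.
* The 0.5 nm contact cutoff is a declared convention taken from the empty
  region of the (d, d<sub>g-ol</sub>) map, exposed as a config knob; the
  "interact" fractions in the reference analysis state no cutoff.
* Residue numbers are taken verbatim from input files; no renumbering.
* Joint histograms store raw counts; log scaling happens only at rendering.
  Out-of-range frames go to an overflow count so total mass is conserved.
* All randomness flows through `numpy.random.default_rng` seeded per stage;
  identical config + seed reproduces every table byte-for-byte.
* Problem sizes in the analysis drivers (262/196 trajectories of 2000
  frames; 200-frame structural fixture; 500-ensemble coverage experiment)
  are the package's chosen desk-scale study conditions; everything scales
  through the specs in `glycoclam.synthetic`.

## Known limitations

* The generator is a two-state process; real LBD dynamics have a continuous
  conformational spectrum, so multi-state model selection (e.g. choosing
  99 vs 6 clusters) is exercised only in the trivial sense that extra
  clusters subdivide two Gaussian basins.
* Short trajectories relative to the lag leave few transition pairs; the
  implied-timescale estimate is noisy (~12% sd at the calibrated study
  scale) and slightly right-skewed because of the log in
  &minus;lag/ln &lambda;.
* No Bayesian MSM error bars, hidden Markov models, PCCA+, transition-path
  theory, kernel density estimation, or FDR control.
* The toy glycoprotein has no hydrogens, realistic bonding, or solvent; the
  PDB reader handles only ATOM/HETATM/MODEL/ENDMDL records (no mmCIF or
  binary trajectory formats).
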