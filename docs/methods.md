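# Methods

## Contact extraction

A frame's contacts are residue pairs (i, j), i < j, whose minimum distance
over the selected atoms is at or below `cutoff_nm` (default 0.5 nm) with
sequence separation `j - i >= min_seq_sep` (default 3). The default atom
selection is all non-hydrogen atoms (`heavy`); `ca` restricts to
alpha-carbons. The heavy-atom minimum is the common convention for
residue-level contact analysis and is exposed as a flag because reasonable
alternatives exist. `min_seq_sep = 3` excludes |i-j| <= 2 neighbours, which
are always within the cutoff and would saturate the series counts, while
keeping i -> i+4 helical contacts visible to the PCA. All coordinates are
handled in nm throughout; PDB input is converted on read.

## Circuit-topology relations

Contacts are closed intervals on the residue index. For two contacts with
disjoint endpoint sets: series iff the intervals are disjoint, parallel iff
one strictly contains the other, cross otherwise. Pairs sharing exactly one
residue endpoint ("concerted" pairs) are frequent at residue resolution, so
instead of dropping them they are mapped to a base class — a shared junction
endpoint (j1 = i2) is series, a shared left/right endpoint (one interval
inside the other) is parallel — and flagged, so `include_concerted=False`
can exclude them from tallies. The classification is symmetric,
translation-invariant, and exhaustive: P + S + X = C(n, 2) for n contacts.

## The CT Folding Score and state classification

Per frame, `Score = P/⟨P⟩ + S/⟨S⟩ + X/⟨X⟩` with ⟨·⟩ the arithmetic means
over all frames of the normalization scope (by default the scored
trajectory itself; pass explicit normalizers to score one replicate against
a variant-wide scope). The ensemble-mean score then equals the number of
retained terms exactly. If a relation type never occurs in the scope, its
term is dropped and the default threshold becomes the number of remaining
terms — this preserves the "score above its own mean" semantics; keeping
the term as 0 would silently deflate every score. A frame is labelled
compact iff its score strictly exceeds the threshold; a score exactly at
the threshold is exposed.

The alternative histogram threshold finds the two largest local maxima of
an `n_bins` (default 50) score histogram and returns the center of the
lowest bin strictly between them; when several bins tie (deep valleys are
often empty) the mean of the tied bin centers is used. The histogram counts
as bimodal only if that valley drops below half the smaller mode; otherwise
the histogram is treated as unimodal and the mean-score threshold is
returned with a warning. The valley-depth criterion exists because finite
histograms of unimodal data always contain spurious local maxima.

## Dwell-time kinetics

Contiguous equal-label runs become dwell records (duration = run length x
dt). Runs touching either trajectory end are censored and excluded from
histograms and fits by default, since boundary truncation biases
exponential fits short; `include_truncated=True` retains them flagged.
Exponential fits are maximum likelihood on the raw durations — the
single-exponential MLE is the sample mean; the two-component mixture is
fitted by EM from 10 seeded random restarts (best log-likelihood wins,
components reported slow-first). Fitting raw durations avoids binning
choices entirely. Event rates are completed-segment counts divided by total
simulation time; no conversion to activation free energies is attempted
because that requires an attempt-frequency prefactor that is not part of
this analysis.

Note that per-frame threshold classification produces occasional
single-frame label flips, which inflate event counts and add a fast
component to dwell distributions; rates from raw label traces are therefore
upper bounds unless the labels are smoothed or a two-component fit is used
to separate the spurious fast component.

The autocorrelation of a per-frame observable is the standard normalized
estimator (FFT-based, mean removed, normalized to 1 at lag zero); the
half-decay time is the first lag where the ACF drops below 0.5, linearly
interpolated between the bracketing lags. Multi-replicate ACFs are averaged
per lag across replicates and never cross replicate boundaries, since
concatenation lets differences in replicate means masquerade as slow decay.

## Geometric observables

Rg is the mass-weighted RMS distance from the center of mass. The Flory
excluded-volume estimate is `Rg = b * N^nu` with defaults nu = 0.6 and
b = 0.22 nm per residue (for N = 58 this gives 2.5 nm); b is a config value
because the per-residue prefactor of disordered chains is itself debated.
SASA uses the Shrake–Rupley construction: per atom, the fraction of 960
deterministic golden-spiral points on the solvent-inflated sphere
(r_vdw + 0.14 nm probe) lying outside every other inflated sphere, times
the sphere area; per-residue SASA sums its atoms. Bondi-style van der Waals
radii are built in; unknown elements raise an error naming the element.

## Contact PCA and free-energy landscapes

PCA operates on raw mean-centered binary contact vectors over the pooled
frames of all variants (one shared contact universe), via full-rank SVD.
Standardizing binary features would up-weight rare contacts, so raw vectors
are the default. Components are sorted by eigenvalue with the
largest-magnitude loading made positive. Per-residue eigenvector
contributions are the sum of absolute loadings of the contacts touching the
residue. Free-energy landscapes are F = -kT ln(count) on a 2-D histogram of
(PC1, PC2), shifted so the occupied minimum is zero, with empty bins masked
(NaN), and with optional fixed ranges so panels for different variants
share one grid.

## Trajectory preprocessing

`filter_equilibrated` discards frames before `discard_ns` and keeps frames
whose offset from `discard_ns` is an integer multiple of the stride within
half the native time step (idempotent; a stride below the native step is a
configuration error). `filter_periodic_image` removes frames where any atom
comes within `min_dist_nm` of any of the 26 neighbouring periodic images of
any atom — exact for boxes larger than the molecule, computed over all
protein atoms. PDB files carry no time axis, so frame times are assigned as
model index x `dt_ns`. Binary trajectory formats are consumed through the
frame-iterator adapter (`ensemble_from_frames`); the package parses no
binary format itself.

## Synthetic data: what it emulates and what it does not

The two-state generator emulates the contact statistics of a ~58-residue
disordered chain: a hidden exposed/compact Markov chain (per-step switch
probability `1 - exp(-k dt)`) where exposed frames draw only short-range
"coil" contacts and compact frames additionally include a fixed set of
nonlocal contacts. Defaults: dt = 0.5 ns (the analysis frame spacing),
k_compaction = 0.01 /ns and k_decompaction = 0.02 /ns (mean exposed/compact
dwells of 100/50 ns, the scale of long-living compaction bursts in IDP
ensembles), coil pool = all pairs with 3 <= |i-j| <= 6 at inclusion
probability 0.12, compact extras = 10 pairs with |i-j| >= 12 at probability
0.8. Bead polymers (0.38 nm virtual-bond random walks, optionally collapsed
into a sphere) cover the geometric observables.

The generator is faithful to contact *statistics*, not to physics: contacts
are conditionally independent given the state, there is no chain
connectivity constraint between frames, no secondary structure, and no
force-field energetics. Passing tests therefore demonstrate that the
pipeline recovers known contact-level ground truth, not that any particular
MD ensemble is described correctly.

## Problem sizes and numerical choices

The shipped tests and the acceptance script run on synthetic ensembles of
1000–5000 frames (up to 4 x 10^5 steps for bare state-chain kinetics),
sizes at which every stochastic check has comfortable margin over its
tolerance while the full suite stays fast. EM uses a relative log-likelihood
tolerance of 1e-10 with at most 500 iterations per restart; ties in the
score histogram valley average the tied bin centers; relation counting on
the pipeline path is vectorized per frame and verified against the explicit
pairwise classifier.

## Known limitations

- Dwell rates from unsmoothed per-frame labels are inflated by
  classification noise (see above).
- The concerted-relation mapping (junction -> S, same-side -> P) is one
  defensible convention; it is configurable but no claim is made that it
  matches any particular prior implementation.
- The periodic-image filter is exact only when the box exceeds the
  molecular extent, the intended regime for solvated single-chain systems.
- Score normalization scope matters: scoring each replicate against its own
  means yields mean 3 per replicate, not per variant; combine replicates
  and pass shared normalizers for variant-level analyses.
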