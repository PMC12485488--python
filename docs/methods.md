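# Methods

This note documents the models, conventions, numerical choices and known
limitations of `helical-validate`, in the spirit of a software methods
section. It states no empirical result that the test suite and
`scripts/acceptance.py` do not themselves compute.

## Helical symmetry model

An ideal helical assembly is generated from one asymmetric unit by the
screw operation S = (rotation by twist θ about the axis, translation by
rise z along it), optionally composed with an axial Cn rotation group.
The i-th symmetry mate sits at azimuth i·θ and height i·z. Parameters
are stored with θ wrapped into (−180°, 180°], z > 0 Å, n ≥ 1.

**Sign convention.** Positive twist = right-handed helix when the axis
points toward increasing slice index. No absolute convention exists in
deposited metadata; what matters is that the generator, symmetrizer and
indexer here share one convention, so a sign mismatch between deposited
values and the map is detected *relative to the map*. True molecular
handedness (map chirality) is explicitly not adjudicated: a mirrored map
with negated twist is self-consistent and classified as such.

**Partial symmetry.** For any integer n ≥ 2, (n·θ mod 360, n·z) is also
a symmetry of the same structure — it simply averages every n-th unit.
The multiplier test accepts n = round(z_dep/z_val) when the
reconstructed rise agrees within 2 % and the reconstructed twist within
1° (defaults chosen so that a published coarse/full pair with errors of
0.38 % and 0.46° is accepted with margin; both tolerances and the search
bound n ≤ 100 are configurable).

## Volume handling

Maps are MRC2014/CCP4 files read and written through gemmi (gzip
accepted). The header's MAPC/MAPR/MAPS words are trusted for the axis
correspondence; `normalize_axes` transposes storage to the standard
order (X fastest, Z slowest) and `orient_helical_axis` brings a
user-named physical axis to the slowest position. When header and data
disagree — which does occur in deposited files — the CLI `--force-axes`
override lets the user assert any of the six permutations rather than
have the code guess.

Coordinates: voxel centers at 0-based indices, physical position =
origin + index × voxel size. The helical axis is taken through the grid
center (N/2 on each transverse axis), matching how helical
reconstructions are boxed; the header origin is carried but not used for
the axis. Anisotropic voxel sizes are rejected outright since every
formula assumes one Å-per-voxel scale.

Invalid voxels are represented as NaN throughout and excluded from all
averages and correlations; they are zero-filled on write. In
particular, `central_slab` marks voxels outside the slab invalid rather
than zero, so re-symmetrization rebuilds the full-length helix purely
from slab content instead of averaging in empty planes.

## Synthetic maps

The generator renders a pseudo-atomic asymmetric unit — a handful of 3D
Gaussians given in cylindrical coordinates — at every symmetry image
whose center falls within 4σ of the box (truncation error < 0.1 % of
amplitude). Two stock fixtures:

- `default_model()`: 64³ voxels at 2.0 Å, three atoms at radii 16/22/10 Å
  with σ = 2.6–3.0 Å. Distinct radii and azimuths break accidental
  rotational symmetry of the unit itself. Builds in ~5 ms.
- `amyloid_model()`: 64³ at 1.25 Å (80 Å box), atoms at radii 20–30 Å
  with σ = 1.4–1.5 Å. Emulates a fibril whose ~4.8 Å axial repeat is
  actually resolved, as in real sub-4 Å fibril maps; the default
  fixture's wider Gaussians would smear consecutive rungs into
  continuous ridges and no indexing method could recover the repeat.

Half-maps add independent Gaussian noise scaled to a stated fraction of
the map RMS, from a caller-seeded `numpy` Generator; no global RNG state
is touched. What the fixtures do **not** emulate: CTF and optics,
solvent, B-factor falloff, per-particle disorder, masking artifacts.
Passing tests therefore demonstrate correctness of the symmetry
analysis, not robustness to microscope physics.

Study-scale conditions used by the test ensembles (chosen once as
desk-scale but representative): 64³ boxes; noise 0.15 × RMS for
classification fixtures (a clean but not noiseless map); noise 2.0 × RMS
for the FSC experiments, placing the unsymmetrized half-map resolution
(~7.5 Å) well away from both the signal band and Nyquist so symmetry
gains are measurable; parameter-recovery ensembles draw twist uniformly
in (−179°, 179°] and rise in [3, 20] Å on the 80 Å fixture (a quarter of
the box, and a range its resolution supports).

## Indexing

Pipeline: radial profile (one-voxel shells about the central axis,
averaged over slices) → radius estimate (density-weighted mean over
shells above 50 % of the profile maximum — robust to hollow vs solid
filaments) → cylindrical band [0.7r, 1.3r] sampled at ~one radius per
voxel and averaged → unwrapped (φ, h) image → 2D autocorrelation →
lattice peak selection.

The autocorrelation is circular in azimuth (the cylinder wraps) and
zero-padded axially with per-lag overlap renormalization (unbiased
estimate); axial lags beyond half the box are discarded as too poorly
supported. Peaks are local maxima above 0.25 of the origin value with a
minimum separation of (2°, 2 Å) to suppress sampling-scale ripple.

**Peak selection.** The textbook rule — take the off-equator peak with
the smallest |Δh| — is necessary but not sufficient on realistic maps,
because the autocorrelation of a multi-atom unit also contains
*cross-peaks* at intra-unit atom-pair offsets composed with the lattice,
typically a fraction of the unit height below each true lattice point.
Three refinements make the rule robust:

1. **Screw-generator harmonic filter.** A candidate (Δφ, Δh) must carry
   correlation support at (2Δφ, 2Δh) and (3Δφ, 3Δh) (when inside the lag
   window) — a true generator's lattice repeats; cross-vectors do not.
   Conversely a candidate whose harmonic support clearly *exceeds* its
   own correlation (by > 0.15) is rejected: that signature arises when a
   weak cross-vector's harmonics coincidentally land on genuine lattice
   points, and is impossible for a true generator, whose first lattice
   point is its strongest.
2. **Score-resolved ties.** Surviving peaks within two axial steps of the
   equator-nearest one are treated as one group and resolved by highest
   correlation (the full-unit self-overlap), then smallest |Δφ|.
3. **Sub-sample refinement.** The chosen peak is refined by separable
   parabolic interpolation (shift clamped to one sample per axis),
   removing the half-step quantization.

The twist sign is read from the Δh > 0 half-plane representative. With
Cn > 1 the lattice point at (θ − k·360/n, z) is an equally valid
generator; the reported twist is the group representative with the
smallest |Δφ| among equal-score ties, which is equivalent modulo Cn.

**Cn detection** correlates the map with itself rotated by 360/k for
k = 2…12 (the cap is configurable). Rotations that divide the true
order are exact symmetries and form a plateau of near-maximal
correlations; the result is the largest k on that plateau (within 0.05
of the best, above a hard floor of 0.75). A plain threshold is not
enough: azimuthally smeared maps correlate well at many angles, just
measurably below the exact symmetries.

**Failure and retry.** Maps without detectable helical order (noise,
partial/focused reconstructions) raise an indexing error; the pipeline
driver retries over a sampling grid {1°, 0.5°} × {1, 0.5, 0.2 Å} before
declaring the entry not validated. Detected rises below one voxel are
discarded as unresolvable on the grid and trigger the same retry.

## Metrics and classification

The vector metric embeds each parameter set as the chord displacement
v = (r·cos θ − r, r·sin θ, z) of a point at the filament radius (the
radius measured from the map itself, not a constant). The chord form is
continuous across the ±180° wrap, satisfies the metric axioms, and is
deliberately insensitive to the sign of small twists: ±0.4° at r = 50 Å
differ by ~0.70 Å, i.e. far below any realistic resolution threshold —
handedness of thin-twist fibrils cannot be decided this way, and the
cascade relies on the correlation scores there instead. Two sets are
"similar" when their distance is below the reported resolution (fallback
2 × voxel size when no resolution is given).

Symmetrize-and-correlate cuts the map to a central slab of three times
the larger of the two rises (falling back to the full map when that
exceeds the box), symmetrizes under each parameter set with transforms
spanning the full axial extent, and computes both Pearson correlations
over the *shared* valid mask so the scores are directly comparable.
"Significantly higher" is cc_val − cc_dep > 0.1 and "both low" is
< 0.5, both configurable.

The cascade order (consistent → swapped → sign → partial → incorrect)
puts specific, cheap explanations first so near-degenerate pairs are not
relabelled; a swap is only considered when the swapped reading puts a
physically sensible rise on the grid (> voxel size, < box height),
which protects small-twist amyloid entries from numeric coincidences.
Class assignments on clean fixtures are stable under ±20 % perturbation
of all thresholds (tested).

## FSC

Shells are one Fourier voxel wide; per shell the real part of the
normalized complex cross-spectrum is reported. No masking and no curve
correction are applied. Resolution is the first crossing below 0.143,
linearly interpolated between shells; curves that never cross report the
Nyquist limit with a flag. First-crossing (not last) is used because
post-crossing oscillations are noise.

## Known limitations

- Only the *global* symmetry is validated. Assemblies with different
  symmetries in different radial regions (e.g. a core whose symmetry is
  a multiple of the sheath's) are driven by the dominant region; their
  per-region validation is out of scope.
- Handedness is validated only relative to the map, never absolutely.
- Dihedral symmetry, seam-containing (non-integer start) helices, and
  layer-line (Fourier–Bessel) indexing are not implemented.
- The classifier's `incorrect_values` vs `not_validated` boundary
  depends on the correlation thresholds; genuinely ambiguous entries
  (low-order maps, tiny boxes) land in `not_validated` by design.
- Synthetic fixtures omit microscope physics (see above); quantitative
  FSC gains on real half-maps will differ from the synthetic ones.
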