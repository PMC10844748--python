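# Methods

## Mass arithmetic

Peptide masses are monoisotopic throughout: the neutral mass is the sum of
residue masses (20 standard residues) plus one water (18.010565 Da) plus
site-resolved modification deltas; m/z = (M + z·1.007276)/z. The built-in
modification set covers methyl (+14.01565), dimethyl, trimethyl, phospho
(+79.96633), carbamidomethyl, acetyl and oxidation. Dimethyl and trimethyl
are exact multiples of the methyl delta, so a PRM series for a lysine site
is an arithmetic progression with spacing Δme/z. Fragment ions follow the
standard b/y (and a = b − CO) conventions, with modification deltas counted
only when the modified position falls inside the fragment; the −H₃PO₄
neutral loss (−97.976896 Da) is available as a flag for phosphopeptide
fragments. Methyl-class modifications are restricted to lysine and phospho
to serine/threonine unless a permissive flag is set; full precision is kept
internally and two decimals are used only for display.

## XIC quantification

An XIC retains observations with |m/z − target|/target ≤ tol (default
10 ppm), optionally restricted to an rt range; co-timed retained
intensities are summed before integration, since profile-mode data can
carry several m/z samples per scan. Areas are trapezoidal over the raw
points — no smoothing, peak fitting or baseline subtraction — which is
reproducible and matches manual XIC practice; a series with fewer than two
points has zero area. Per-state areas are normalised to fractions; a
zero-signal sample yields an explicitly undefined profile rather than NaNs
propagating silently. The weighted methylation fraction divides Σk·p_k by
a reference maximum that is an explicit parameter (2 when dimethylation is
the biological end state, as for yeast K316 in vivo; 3 for trimethylation,
as in vitro); a profile exceeding its reference (p₃ > 0 with r = 2) is
flagged, never clamped. Precursor-window collisions between states at the
working tolerance are an error naming the colliding pair. Quantification
can sum fragment-ion XIC areas per state instead of the precursor area;
with a single fragment equal to the precursor window the two modes
coincide. No rt integration range is imposed by default; callers that know
the elution window should pass one, since with additive noise the
full-gradient baseline contributes a small area to every state.

## Statistics

Many-to-one comparisons use ordinary one-way ANOVA plus Dunnett's test;
the adjusted p-values come from the multivariate-t distribution of the
contrasts (scipy), whose CDF is evaluated by quasi-Monte Carlo — a fixed
internal generator seed makes reports byte-reproducible. Planned pairwise
comparisons use Welch's t with the Šídák correction 1 − (1 − p)^m. Welch's
test returns p = 1 by convention when both groups are constant and equal.
Initial-rate fits are OLS restricted to a stated x range; constant y
returns slope 0 with r² = 0 by convention. Dose-response data are fitted
to the four-parameter logistic y = bottom + (top − bottom)/(1 + (d/EC50)^h)
on the linear dose axis, so 0-dose points need no pseudo-dose; the Hill
slope is constrained positive (the model is then continuous at d = 0) and
response direction is carried by the top/bottom ordering. Fits try several
starting points and keep the best least-squares solution; non-convergence
raises an error with the optimiser message, and constant responses return
a degenerate flag with r² = 0. Reports annotate significance with the
usual star convention (ns, ∗ ≤ 0.05, ∗∗ ≤ 0.01, ∗∗∗ ≤ 0.001, ∗∗∗∗ ≤ 0.0001)
at α = 0.05 by default.

## Structural checks

Structures are read with gemmi from PDB or mmCIF, keeping author chain ids
and residue numbering; waters, non-protein hetero compounds and hydrogens
are dropped, and alternate locations resolve to the highest-occupancy
conformer (ties to the alphabetically first altloc). Crosslink restraints
are Cα–Cα Euclidean distances with an inclusive limit (default 30 Å, the
DSSO convention); unresolvable sites are collected into an error report
rather than dropped. Superposition is least-squares rigid (Kabsch via SVD
with a determinant correction so the rotation is always proper), pairing
Cα atoms by residue-number intersection — sequence-independent pairing is
out of scope since the intended comparisons align identical sequences.
Selections with fewer than 3 paired atoms, or collinear ones, are
rejected. Conformational remapping treats the structure as rigid units:
the anchor domain plus all atoms outside the hinge domain (including
bound passenger chains) receives the anchor's transform, and the hinge
domain its own; internal geometry of each unit is exactly preserved and
the operation is idempotent against the same reference. Domain boundaries
are caller-supplied configuration, not code, because they are a judgment
about the particular protein. Polar contacts pair N/O atoms across two
chains within a cutoff (default 3.5 Å, hydrogen-bond-like), reporting the
closest atom pair per residue pair; pocket residues are partner-chain
residues with any heavy atom within a cutoff (default 4.5 Å) of the probe
side chain (Gly probed via Cα). Both are exact all-pairs scans — the
models involved are small enough that no spatial index is warranted.

## Synthetic data

The trace generator emulates a targeted acquisition of the four
methylation states of a 19-residue GluC-type peptide at z = 3: each state
elutes as a Gaussian (default σ = 2 s around 60 s, sampled every 0.5 s
over ±30 s) at its theoretical m/z with per-scan Gaussian ppm jitter
(default 2 ppm, well inside the 10 ppm analysis window) and additive
Gaussian intensity noise truncated at zero; peak height is 1000 units per
unit abundance. The defaults describe a clean, well-behaved acquisition;
real data additionally show peak tailing, retention-time drift between
runs, interfering isobaric species and detector saturation, none of which
is modelled — passing recovery tests therefore demonstrate correctness of
the quantification arithmetic, not robustness to pathological
chromatography. Toy complexes are geometric Cα scaffolds, not physically
plausible proteins: two zig-zag chains with planted crosslink distances
imposed exactly by construction and a hinged domain rotated by a chosen
angle in the emitted reference conformation — sufficient for the
distance, superposition and remapping contracts. Group tables are normal
replicates; dose-response data are 4PL evaluations plus seeded noise.
Every generator is a pure function of its spec and seed and returns its
ground truth alongside the data.

## Numerical and design choices

- Proton mass 1.007276 Da; monoisotopic masses reproduce the four-state
  PRM series of the K316 GluC peptide to two decimals.
- Fractions must sum to 1 within 1e-9 when defined; superposition
  rotations are proper to 1e-6; remapping is idempotent to below 1e-6 Å.
- The pipeline config is JSON (not TOML): the config contract demands a
  lossless file round-trip and the standard library writes JSON natively.
- All randomness flows from explicit seeds; the test problem sizes
  (50 recovery traces, 1000 null tables, 30 dose-response seeds, toy
  complexes of ~35 residues) were chosen as the smallest sets that make
  the Monte-Carlo assertions stable.

## Known limitations

- No peak detection or deconvolution: overlapping isobaric species within
  a window are summed, by design.
- Precursor-only and fragment-sum quantification are supported, but
  fragment lists must be supplied by the caller; no spectral library.
- mzML input is not parsed; the canonical trace format is long-form TSV
  (rt_s, mz, intensity), which any vendor converter can produce.
- Remapping assumes the caller's domain definitions describe genuinely
  rigid units; a hinge placed inside a rigid unit will shear the model at
  the boundary (backbone continuity across the hinge is not enforced).
- Dunnett p-values are Monte-Carlo evaluations of the multivariate-t CDF
  and agree with tabulated values to ~1e-3, not machine precision.
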