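# Methods

## Model

`kd2` describes the neighbourhood of a pixel location — a *point of
interest* (POI) — in a gray-scale image by six numbers that are invariant
under translation, rotation and (approximately) scaling of the local
pattern, and retrieves similar neighbourhoods from a pre-built index by
nearest-descriptor search.

The construction rests on the Krawtchouk polynomials `K_n(x; p, N)`,
orthogonal on the integer grid `{0, ..., N}` with respect to the binomial
weight `w(x; p, N) = C(N, x) p^x (1-p)^(N-x)`, with squared norms
`rho(n; p, N)`.  Only the centred family `p = 1/2` up to order 3 is used;
at `p = 1/2` the norm has the closed form `rho(n) = n!(N-n)!/N!`.  The
normalized family `Kbar_n = K_n sqrt(w / rho)` is orthonormal, and the
separable products `Kbar_n(x) Kbar_m(y)` form a moment basis whose
Gaussian-like envelope `W_c(x, y) = sqrt(w(x) w(y))` concentrates on the
centre of an `S x S` window.  This envelope is what makes the moments
*local*: for `S = 150` its effective radius is roughly 25 px, so a
descriptor sees only the pattern around its POI, not the whole window.

Given a square crop `f_s` with the POI at window coordinates
`(x_s, y_s)`, the pipeline is:

1. **Weight shift.** The envelope is translated so its peak sits on the
   POI: `W_s(x, y) = W_c(x - x_s + c, y - y_s + c)` with
   `c = (S-1)/2`, indices rounded to the nearest grid point and
   out-of-grid positions set to zero.  (The shift direction matters: the
   lookup must *subtract* the POI offset so the peak lands on the POI —
   the mirrored sign convention destroys rotation invariance because the
   envelope then sits on the wrong side of the pattern.)  For even `S`
   and an integer POI the half-up rounding aligns the discrete envelope
   exactly with a pattern centred between pixels, which is the common
   case for even-sized patterns pasted centred on an integer location.
2. **Auxiliary image.** `f~ = f_s * W_s`, elementwise.
3. **Moment normalization.** From the raw moments of `f~` we take the
   mass `M00`, centroid `(xc, yc)` and central moments up to order 3,
   and the principal-axis angle
   `theta0 = atan2(2 mu11, mu20 - mu02) / 2`.  Each pixel is mapped to
   the normalized frame

       u = gamma [ (x - xc) cos(theta) + (y - yc) sin(theta) ] + c
       v = gamma [ -(x - xc) sin(theta) + (y - yc) cos(theta) ] + c

   with `gamma = sqrt(beta / M00)`, and the invariant moments are
   `lambda_ij = (beta / M00) sum f~(x, y) u^i v^j` for `i, j = 0..3`.
   `beta` is a fixed reference mass; by construction `lambda_00 = beta`
   and `lambda_10 = lambda_01 = beta c`.
4. **Descriptor assembly.**

       Q_nm = [rho(n) rho(m)]^(-1/2) sum_{i<=n, j<=m} a_{i,n} a_{j,m} lambda_ij

   where `a_{i,n}` are the monomial coefficients of `K_n`.  Because the
   normalization pins mass, centroid and the mixed second moment,
   `Q_00 = beta` and `Q_01 = Q_10 = Q_11 = 0` identically — they carry
   no information and are discarded.  The descriptor is

       V = [Q_20, Q_02, Q_12, Q_21, Q_30, Q_03].

   Retrieval ranks indexed descriptors by the squared Euclidean
   distance `d(V_Q, V_DB) = sum (V_Q - V_DB)^2`, raw and unweighted.

### Principal-frame disambiguation

`theta0` is defined only modulo pi/2.  Among the four candidates
`theta0 + k pi/2` the implementation keeps those with
`mu'_20 >= mu'_02` in the rotated frame and then requires the *dominant*
rotated third moment — `mu'_30` if `|mu'_30| >= |mu'_03|`, else
`mu'_03` — to be positive; if both are below tolerance
(`1e-9 * M00 * S^3`) the smallest-magnitude candidate wins.  Preferring
the dominant third moment instead of unconditionally testing `mu'_30`
matters for patterns that are mirror-symmetric about their principal
axis: for those `mu'_30` vanishes up to resampling noise, and a rule
keyed on its sign would let that noise pick the frame, flipping the
odd-order descriptor components between a pattern and its rotated copy.
The dominant-moment rule is deterministic and reduces to the naive rule
whenever `mu'_30` genuinely dominates.

Rotational ambiguity (`mu11 = 0`, `mu20 = mu02`) yields `theta = 0` with
an `ambiguous` flag; for such isotropic patterns the invariants do not
depend on the frame, so any choice is consistent.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `S` | pattern-dependent (150 in the benchmark) | window size in pixels; also fixes the envelope width (std ~ `sqrt(S)/2` per axis under the square root) |
| `p` | 0.5 | basis parameter; fixed (off-centre POIs are handled by shifting the weight) |
| order | 3 | highest moment order; a single constant in `kd2.basis` |
| `beta` | `S^2/12` | reference mass of the normalized pattern; a free calibration constant that must be identical for index and query (`S^2/12`, the variance of a uniform spread over the window, keeps `gamma` near 1 for typical dense patterns) |
| degeneracy threshold | `1e-12 * S^2 * 255` | weighted mass below which a window is rejected as blank instead of producing NaN descriptors |
| grid stride | 8 | default POI spacing when indexing an image by grid rather than explicit points |
| variance filter window | 40 | subregion size for the local-vs-global variance pre-filter used on noisy micrograph-like images |

Because `gamma` couples the reference mass to the measured mass, the
descriptors are invariant to spatial rescaling of a pattern (mass scales
with area) but not to brightness rescaling; index and query must share
the intensity convention, and dark-on-light material must not be mixed
with light-on-dark.

## Synthetic benchmark

The fixture module replicates a local-retrieval experiment: 9 distinct
60x60 gray-scale icons are rotated through 12 angles (0..330 in steps of
30), scaled by 0.8 / 0.9 / 1.0, and the 9 x 12 x 3 = 324 transformed
copies are placed, via a seeded permutation, on the 81 slot centres of a
9x9 grid in each of four 600x600 black canvases.  Slot centres sit at
`round((2i+1) * 600/18)`, i = 0..8.  Indexing uses the 81 slot centres
per canvas with `S = 150`; the queries are the 9 untransformed icons
centred in 150x150 frames.  Scaling is applied before rotation; both are
bilinear with zero fill.

Icons are procedural filled silhouettes (ellipse, triangle, pac-man,
D-shape, teardrop, T, offset donut, notched block, crescent) with seeded
shape jitter, emulating the dense filled clip-art drawings such
benchmarks are usually built from.  Each shape is mildly smoothed
(Gaussian, sigma 1) so bilinear resampling is stable, and the set must
pass a separation criterion before use: the squared descriptor distance
between any two icons must exceed 10x the worst distance between an icon
and its own 30-degree-rotated copy, otherwise generation retries with
fresh jitter (up to 5 attempts).  Shapes are deliberately anisotropic
with a well-determined third moment, because patterns with near-isotropic
weighted second moments have noise-driven principal frames and therefore
unstable descriptors — a genuine property of the method, not of the
fixture.

**Noise protocol.**  `add_salt_pepper(density)` sets a seeded fraction of
pixels, chosen uniformly without replacement, to 0 or 255 with equal
probability.  In the degraded benchmark the *whole dataset* is degraded:
every database canvas and every query frame receives an independent
noise realization at the same density, and retrieval is scored
noisy-against-noisy.  This models searching within corrupted data (both
the query patch and the database come from the same degraded imagery).
Matching a pristine query against a heavily degraded index is a harder
problem that this descriptor does not solve well — see Limitations.

**What the fixture does not emulate:** real clip-art texture, cryo-EM
image statistics (no CTF, no Gaussian noise model, no particle overlap),
anti-aliased rendering, or sub-pixel placement.  Passing the benchmark
shows that the invariance and ranking machinery works under controlled
geometric transforms and impulse noise; it does not certify retrieval
quality on any particular class of real images.

## Problem sizes

The test suite and the acceptance script run the full-size benchmark
(four 600x600 canvases, 324 indexed subimages, S = 150) for three seeds
and noise densities {0, 0.10, 0.30}; one seed-density run indexes 324
subimages plus 9 queries and completes in about a second on one core.
Smaller specs (3 icons, one 200x200 canvas, S = 100) are used for
API-level and CLI tests.

## Numerical choices

- All binomial quantities are computed via log-gamma and exponentiated;
  naive factorials overflow beyond `N ~ 170`.
- Moments are computed by separable vectorized accumulation and verified
  against a brute-force double loop in the tests (1e-9 relative).
- Weight shifting is nearest-integer; POIs are integer by contract and
  fractional inputs are rounded on entry.
- Coordinate rotation (not pixel resampling) realizes rotation
  invariance inside the descriptor; resampling exists only in the
  fixture generator.
- Index files store descriptor components with 8 significant digits
  (`%.8g`), which round-trips rankings unchanged.
- Tie-breaks in ranking are deterministic by `(image_id, x_p, y_p)`, so
  search results do not depend on index insertion order.

## Limitations

- **Clean-query vs degraded-index matching.**  Salt-and-pepper noise
  adds weighted mass to every window, which inflates `M00`, shrinks
  `gamma`, and contracts every descriptor component nonlinearly (by a
  factor around 2.5 at 30% density on dark-background material).  All
  indexed descriptors drift coherently, but a clean query does not share
  the drift, so squared-Euclidean rank-1 accuracy against a 30%-degraded
  index falls to roughly 75% on the benchmark regardless of icon design.
  When query and database share the degradation (the benchmark protocol),
  rank-1 accuracy stays above 92%.
- Scale invariance is approximate: the envelope does not rescale with
  the pattern, so 0.8x copies match to about 5% relative, not exactly.
- Brightness is part of the signature (see above); descriptors are not
  contrast-normalized.
- Patterns whose weighted second moments are nearly isotropic but whose
  higher structure is not (e.g. thin rings larger than the envelope)
  have unstable principal frames and hence noisy odd components.
- The absolute values of `V` depend on the calibration constant `beta`
  and on the frame conventions; they are internally consistent but not
  comparable to descriptor values produced by other implementations
  with different (unpublished) constants.
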