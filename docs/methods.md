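# Methods

## The similarity index

`chemsi` measures chemical similarity between two molecules A and B as a
weighted combination of four blocks:

```
SI(A,B) = Sb(FP_A, FP_B)^w_fp * Snb(CD_A, CD_B)^w_cd
          * Snb(HD_A, HD_B)^w_hd * Snb(FG_A, FG_B)^w_fg ,
w_fp + w_cd + w_hd + w_fg = 1
```

* **FP** — a binary fingerprint, compared with one of 44 binary similarity
  coefficients `Sb` over the confusion counts (a, b, c, d).
* **CD** — 35 constitutional descriptors (atom/bond counts, sums and
  heavy-atom means of carbon-scaled atomic constants).
* **HD** — the 11 hetero-atom counters, a subset of CD split out so that
  "same skeleton, different heteroatoms" can be weighted separately.
* **FG** — occurrence counts (not booleans) of a 154-entry functional-group
  SMARTS catalog. Counting occurrences is the information a plain
  fingerprint lacks: a fingerprint bit cannot distinguish one hydroxyl from
  two, the FG block can.

The three non-binary blocks are compared with one of 6 continuous
coefficients `Snb`.

The product form is read as a *weighted geometric mean*: each block's
similarity enters as `s^w`, a factor with weight 0 contributes 1 (so the
convention 0^0 = 1 applies), and a zero similarity on a positively weighted
block zeroes the index. A weighted arithmetic mean (`sum w_k s_k`) is
available via `mode: arithmetic` for sensitivity analysis; both modes are
symmetric and bounded in [0, 1].

The shipped default configuration is `extended`
fingerprint, binary coefficient 37 (Maxwell–Pilliner), non-binary
coefficient 3 (Bray–Curtis), weights (fp, cd, hd, fg) = (0.4, 0.35, 0.1,
0.15), geometric mode.

## Fingerprint families

Nine families are registered. Four are hashed linear-path fingerprints: all
simple paths of 0–7 bonds are enumerated, each path canonicalised as the
lexicographic minimum of its forward/backward element+bond-symbol string,
and hashed (`blake2b`, 8-byte digest, modulo the bit length — fixed and
platform-stable) onto 1024 bits by default:

| family | variation |
|---|---|
| `default` | aromatic-perceived bond symbols `- = # :` |
| `extended` | `default` + 14 appended ring bits: presence of ring sizes 3–8 and the SSSR ring count (unary, capped at 8) |
| `graph_only` | path strings without bond symbols |
| `hybridization` | Kekulé bond orders, no aromatic symbol |

Five are structural keys driven by ordered SMARTS catalogs (bit *i* set iff
pattern *i* matches): `estate` (79 Kier–Hall-style valence-state atom types,
shipped as a TSV), and `maccs` (166), `substructure` (307), `pubchem` (881),
`klekota_roth` (4860). The published definitions of the last four are
third-party data; they are represented here by **synthetic stand-in
catalogs** — a deterministic enumeration of linear-chain SMARTS over common
organic elements, truncated at each family's published length. The family
contract (fixed length, one pattern per bit, per-pattern match semantics)
is preserved and any catalog can be replaced by a user TSV
(`index<TAB>SMARTS<TAB>name`). No attempt is made to reproduce CDK's exact
bit assignments; conclusions drawn from these keys concern family
*mechanics*, not the published bit definitions.

## Similarity coefficients

The 44 binary coefficients follow the Todeschini et al. (2012) roster and
numbering (Maxwell–Pilliner is no. 37, Jaccard/Tanimoto no. 3, the
Consonni–Todeschini log forms nos. 39–43, ...). The registry documents each
formula and its source note. Uniform conventions:

* `(b, c)` is canonicalised to `(min, max)` before evaluation. This makes
  the orientation-dependent forms (Dice 1/2, Peirce 1/2, Cole 1/2)
  symmetric and is a no-op for all others.
* Raw ranges are mapped into [0, 1]: `[-1, 1]` forms are rescaled
  `(s+1)/2`; unbounded `[0, inf)` forms (Forbes, Kulczynski 1, Mountford,
  Fossum, Sokal–Sneath 3) are mapped `s/(1+s)`; Harris–Lahey (range
  `[0, p]`) is divided by `p`; Dennis (range `[-sqrt(p)/2, sqrt(p)]`) is
  shifted and scaled by its bounds; everything is clipped to [0, 1], which
  also guards the Cole forms whose raw values can leave `[-1, 1]`.
* Degenerate inputs: identical all-zero fingerprints score 1; identical
  inputs score 1 for every coefficient whose formula attains its maximum at
  identity (`self_unit` flag, 35 of 44); an undefined 0/0 otherwise
  resolves to 0.5 for correlation-type forms and 0 for the rest; additive
  two-block forms (Rogot–Goldberg, Hawkins–Dotson, Sokal–Sneath 4,
  Harris–Lahey) resolve empty-block terms to their identity limits.

Nine coefficients — Russell–Rao, Forbes, Faith, Michael, Fossum, Dennis,
Dispersion, CT3, CT5 — do **not** score 1 on identical inputs; that is a
property of their published formulas (e.g. Russell–Rao is `a/p`), not a
defect, and the self-similarity contract `SI(A,A) = 1` is therefore
guaranteed only for configurations using the 35 identity-calibrated
coefficients.

The 6 non-binary coefficients follow the Holliday et al. numbering. The
three distance forms are returned as similarity complements with 0/0
component terms dropping out: Mean Canberra
`1 - (1/n) sum |x-y|/(x+y)`, Divergence `1 - (1/n) sum ((x-y)/(x+y))^2`,
Bray–Curtis `1 - sum|x-y| / sum(x+y)`. The association forms are
Dice `2 sum xy / (sum x^2 + sum y^2)`, the continuous Sokal–Sneath
generalisation `sum xy / (2 sum x^2 + 2 sum y^2 - 3 sum xy)`, and
Cosine/Ochiai. Descriptor vectors are compared **raw** (no per-descriptor
scaling); Bray–Curtis on raw CD vectors is therefore dominated by the
large-magnitude descriptors (MW, Sv, Se), which is the intended "global
size and composition" reading of that block. An optional per-dataset
min–max scaling flag exists and is off by default.

## Atomic constants

`data/atomic_constants.tsv` carries, per element: standard atomic weight,
van der Waals volume relative to carbon computed as `(r/1.70 Å)^3` from
Bondi radii, Sanderson electronegativity relative to carbon (2.746), and
static polarizability relative to carbon (1.76·10⁻²⁴ cm³). Sums (Sv, Sp,
Se) run over heavy atoms only; the means (Mv, Mp, Me) divide by the
heavy-atom count. SCBO counts aromatic bonds as 1.5. Hydrogens are implicit
throughout (H-depleted graph); nH and nAt derive from implicit-H counts.
Salts and mixtures are reduced to their largest fragment; stereochemistry
is parsed but ignored (no key here is stereo-aware).

## Read-across model

A query's endpoint is the SI-weighted mean of the experimental values of
its k = 3 most similar training compounds: `y_hat = sum SI_i y_i / sum
SI_i`. Ties in SI break by ascending compound id, making runs fully
deterministic; if all three similarities are zero the prediction falls back
to the unweighted mean and is flagged low-confidence. Validation is
leave-one-out; quality is summarised by RMSE and R² in the
coefficient-of-determination sense `1 - SS_res/SS_tot` (the squared-Pearson
reading is reported alongside in the detailed output, since the two are
distinguishable only by convention). A constant-value dataset (SS_tot = 0)
reports r2 = 1 with a `degenerate_variance` flag. Duplicate training
structures are not collapsed. k is exposed as a flag but 3 is the model.

## Two-stage evaluation

Stage 1 sweeps fingerprint family × binary coefficient with weights
(1, 0, 0, 0) — a pure fingerprint benchmark; the descriptor blocks are
switched off by the 0⁰ = 1 convention. Stage 2 fixes the winning pair and
sweeps weight tuples × non-binary coefficient. The weight lattice is
w_fp ∈ [0.3, 1.0] step 0.1; w_cd ∈ [0, 0.4] step 0.05; w_hd, w_fg ∈ [0, 1]
step 0.05, under the exact-sum-1 constraint (enumerated over rationals, so
no float drift; 338 tuples, hence 2028 stage-2 runs over 6 coefficients).

Each run's per-dataset R² and RMSE are min–max scaled **across the batch
being ranked** (the only self-contained choice), RMSE scaled values are
complemented (1 − scaled), and two scores are attached: DES, the geometric
mean of the scaled parameters (a run scoring 0 on any parameter gets
DES = 0), and UTI, their arithmetic mean. With two datasets the exponents
and weights are all 0.25. A metric with zero spread across the batch is set
to 1 for every run, with a warning. Ranks break ties by batch order. The
grid engine evaluates coefficients on precomputed pairwise confusion-count
and key matrices; its neighbour selection and metric code are shared with
the scalar read-across path, and a test pins the two paths to 1e-12
agreement.

## Synthetic fixtures

The packaged library holds 60 curated small organics arranged as 15
same-formula isomer clusters (4–5 members): alkanes, alcohols, diols,
amines, diamines, alkyl chlorides/bromides/iodides, halobenzenes,
methylbenzenes, methylphenols, ketones, thiols/sulfides, organophosphorus
esters and alkylboronic acids. The clustering is a design requirement, not
an optimisation: read-across is only defined inside an applicability
domain, so a fixture that validates it must guarantee every compound keeps
close structural neighbours even after seeded sub-sampling; the
endpoint-extreme iodide cluster carries five members for sampling
resilience. The clusters jointly cover all nine HD hetero-atoms, and
several member pairs differ only in the multiplicity of one functional
group (butanol/butanediol, toluene/xylene, ...), exercising the FG
count-versus-boolean distinction.

The generator attaches `y = 0.01·MW − 0.5·nHet + N(0, σ²)` with σ = 0.1
and seed 42 by default, over a seeded 50-of-60 sample. The property is
deliberately a function of descriptors the SI itself sees, so LOO recovery
(R² ≈ 0.95 at σ = 0.1) is an end-to-end sanity check of the whole
pipeline — it says nothing about real BCF or logP endpoints, whose
distributions, noise structure and structure–activity cliffs the fixtures
do not emulate. Problem sizes throughout (50-compound recovery fixture,
30-compound grid benchmark) were chosen so the full combinatorial sweeps
remain cheap desk-scale computations.

## Known limitations

* The four large key catalogs are synthetic stand-ins; similarity values
  from those families are internally consistent but not comparable to
  CDK/PubChem implementations.
* Descriptor vectors are unscaled, so the CD block is dominated by MW-scale
  descriptors under Bray–Curtis; use the scaling flag if per-descriptor
  balance is wanted.
* No applicability-domain score beyond the SI itself, no uncertainty
  intervals, no structure standardisation beyond largest-fragment
  selection.
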