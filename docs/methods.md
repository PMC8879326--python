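# Methods

## Problem setting

`foulqsar` implements a ligand-based virtual-screening pipeline for binary
antifouling activity: curate a structure library, compute 2D topological and
3D radial-distribution-function (RDF) descriptors, train class-balanced
classifiers with out-of-bag (OOB) validation and importance-based descriptor
selection, and triage a screening library by the predicted probability of
activity. The package ships a synthetic molecule generator with a planted
structure–activity rule so that every stage is testable end to end without
external data.

## Data model and curation

Molecules are lists of atoms (element, 3D coordinates in Å, formal charge,
optional partial charge, tetrahedral parity code) and bonds (index pair,
order 1/2/3/aromatic). SDF I/O is restricted to the V2000 dialect; V3000
blocks are rejected with an explicit error. Standardization keeps the
connected component with the most heavy atoms (ties: larger total mass, then
lowest first-atom index), which strips salts and stray fragments. Identity
for deduplication is a canonical key with a stereo layer — InChI by default,
canonical isomeric SMILES as a faster provider for very large libraries; two
constitutionally identical molecules with unspecified stereocenters collide,
while enantiomers with specified centers do not. Tautomer and mesomer
normalization is deliberately out of scope: the dedup contract is key-level
only.

Activity labels derive from one endpoint per compound: percent inhibition
strictly above 52% is active; EC50/IC50 at or below 25 μg/mL is active
(boundary included). When a compound carries conflicting endpoints the
inactive call wins.

## Partial charges

Charge-weighted descriptors need a consistent, conservative per-atom charge,
not any particular population analysis. The default provider is the
iterative partial equalization of orbital electronegativities (PEOE,
Gasteiger–Marsili) with six sweeps; the scheme transfers charge along bonds
with its canonical 0.5^k per-iteration attenuation and conserves total
charge to machine precision (the module enforces agreement with the summed
formal charge to 1e-6 e). Externally computed charges (e.g. NBO) can be
injected per atom from a CSV, making the provider fully swappable.

## Descriptor engine

All descriptor mathematics is defined in `descriptors.py`; no external
descriptor package stands behind it, so each family is verified in the test
suite against an independently coded brute-force oracle (tolerance 1e-8).

* **Autocorrelations** (Broto–Moreau ATS, centered ATSC, averaged AATS/
  AATSC, Moran, Geary) over heavy-atom pairs at topological lags 1–8, with
  seven weightings: atomic mass, van der Waals volume, Sanderson
  electronegativity, polarizability, first ionization potential, partial
  charge, and intrinsic (E-state) value. Lags with no pair, or zero weight
  variance for the normalized forms, yield missing values.
* **Burden eigenvalues**: the symmetric connectivity matrix with
  carbon-relative weights on the diagonal, 0.1×(conventional bond order)
  (+0.01 if either end is terminal) for bonded pairs and 0.001 elsewhere;
  descriptors are the k smallest/largest eigenvalues (k = 1..5) for six
  weightings (the per-atom intrinsic state uses 2.0 — an sp³ CH₃ carbon — as
  its carbon reference).
* **E-state**: intrinsic states I = ((2/L)²δᵛ+1)/δ perturbed by
  (Iᵢ−Iⱼ)/(d+1)²; shipped atom types are quaternary carbon (ssssC),
  methylene (ssCH2), saturated-environment CH hydrogens (HCsats, computed
  with a hydrogen E-state that substitutes the Kier–Hall atom-level
  electronegativity (δᵛ−δ)/L² for the intrinsic state), and weak
  hydrogen-bond acceptors (divalent ether O and divalent S), each with
  sum/max/min aggregation.
* **WTPT-5**: for every nitrogen, 1 plus the sum over simple paths starting
  there of the product of 1/√(deg·deg) bond weights; 0 without nitrogen.
* **Galvez topological charge indices** GGI/JGI at orders 1–3.
* **Mannhold logP** = 1.46 + 0.11·nC − 0.11·(non-carbon heavy atoms).
* **RDF descriptors**: RDF(r) = Σ pᵢpⱼ·exp(−B(r−rᵢⱼ)²) over unordered atom
  pairs (hydrogens included; partial charges as weights), sampled at 128
  grid points r = 0.1g Å (g = 1..128; r = 0 is excluded as chemically
  meaningless) with fuzziness B = 100 Å⁻², partitioned into three
  descriptor sets by charge-sign pattern: (a) one positive and one negative
  charge, (b) both positive, (c) both negative. Signed products are kept, so
  set (a) is non-positive and sets (b)/(c) non-negative; zero-charge atoms
  belong to no set. An absolute-value mode and a heavy-atom-only flag exist
  for sensitivity analysis.

`featurize` evaluates the enabled families in a fixed column order
(336 autocorrelations, 60 Burden accessors, 5 E-state atom types, WTPT-5,
JGI₁₋₃, Mannhold logP, 384 RDF bins = 790 columns by default), records a
column manifest (family, weighting, lag/bin, grid radius), and applies the
missing-value policy: by default missing entries become 0 and are flagged in
a boolean mask (constant imputation is harmless for tree ensembles and the
mask preserves auditability); a strict mode raises instead.

## Models and evaluation

The central estimator is a **balanced random forest** built on scikit-learn
decision trees: each of 500 fully grown trees (√p feature subsampling per
split) is trained on a per-class bootstrap whose size equals the
minority-class count — for a 57 active / 70 inactive training set every
tree sees 57 + 57 draws — so majority-class preference is removed without
reweighting. OOB votes are accumulated per molecule; `Prob_active` is the
fraction of votes for the active class, and OOB confusion counts give the
internal validation metrics. Descriptor importance is the permutation mean
decrease in accuracy: per tree, OOB accuracy minus OOB accuracy after
permuting one descriptor among the OOB molecules, averaged over trees.
Selection retrains the forest on the top-k descriptors for
k ∈ {12, 25, 50, 100, 150, 200, 250} and picks the k maximizing OOB Q with
MCC as tie-break (the tie rule is this package's choice).

Metrics follow the standard definitions: SE = TP/(TP+FN), SP = TN/(TN+FP),
Q = (TP+TN)/n, MCC with the usual four-factor denominator; any zero
denominator is reported as an explicit undefined flag (rendered "-" in
per-cluster tables). `counts_from_rates` inverts printed SE/SP back to the
unique integer confusion counts given the class sizes, with a configurable
tolerance (default 5e-4, i.e. 3-decimal rounding).

The SVM contract is an RBF C-SVM with the tuned cost/width defaults
C = 1e7, γ = 1e-8, balanced class weights and pairwise-coupling probability
calibration; the MLP contract is a 200-200-2 feed-forward network with relu
hidden activations, batch size 36 and 100 epochs of cross-entropy training.
Both scale inputs by default (whether the original workflow scaled is
unknowable; scaling is the package's choice and is configurable). The MLP is
scikit-learn's implementation, so the optimizer is adam and the output layer
a softmax pair rather than Adadelta with a sigmoid unit — an equivalent
two-class parameterization. Majority-vote consensus over an odd number of
models is provided; consensus is not asserted to dominate its members (it
often does not).

## Screening triage

A fitted model scores a featurized library into per-molecule hits. The
confidence threshold θ_conf is defined operationally as the largest
Prob_active among false positives of a labeled hold-out set, so that on that
set every prediction scoring strictly above θ_conf was a true positive; with
no false positive the largest inactive-truth score is used. The shortlist
threshold (default 0.68, boundary included) flags predicted actives for
downstream structure-based work; exports order by decreasing Prob_active
with ties broken by molecule id. μg/mL→μM conversion is 1000·c/MW.

## Synthetic libraries and the planted rule

The generator builds valence-correct molecular graphs from seven scaffold
templates (acyclic chain, O-heterocycle, N-heterocycle, fused bicyclic,
diketopiperazine-like ring, two rings with a carbonyl linker, macrocycle)
standing in for structural clusters I–VII in role only, grows them with a
C-rich palette (N/O/S/Cl/Br minor; grown oxygens as carbonyls), fills
hydrogens, embeds 3D coordinates with deterministic distance geometry
(ETKDG; heavy-atom bonds land in 1.2–1.9 Å, X–H bonds in 0.85–1.3 Å, no
non-bonded pair under 1.5 Å), and assigns PEOE charges.

Activity is planted as: active ⇔ a quaternary carbon is present AND a
strong (+,−) charge pair lies within 4.5–5.5 Å, then flipped with
probability 0.05. Strong means ≥ +0.45 e and ≤ −0.70 e, thresholds chosen
on the PEOE scale so that exactly one planted carbonate carbon and one
planted gem-diolate oxygen pair qualify per molecule (the diolate dianion is
a deliberately synthetic strongly polar probe, not a solution species). The
default library is 45% active (the ~1:1.22 imbalance of a curated
antifouling set) at sizes 10–60 heavy atoms. Inactives mix motif-free
molecules with geometric near-misses (motif present, anchor pair outside
the window, 12.5% of inactives), and the two motif-bearing pools fill
matched heavy-atom-size quotas so molecular size — the dominant driver of
RDF background intensity — never correlates with the geometric half of the
rule. Accepted actives carry their anchor inside the centrally trimmed
window (4.65–5.35 Å), concentrating the planted spikes on a few adjacent
RDF grid points.

What passing recovery tests do and do not show: the generator plants a
signal expressible exactly in the descriptor families the pipeline computes,
with uncorrelated background noise; real activity data have correlated
descriptors, scaffold-confounded labels, assay noise far above 5%, and no
guarantee that activity is a function of the computed descriptors at all.
Recovery results therefore validate the machinery (featurization, balancing,
OOB bookkeeping, importance, selection, thresholds), not expected
performance on experimental sets.

A structural limitation worth recording: mixed-sign RDF bins accumulate
single-signed products, so their magnitude grows linearly with atom count
and the per-bin background of a 60-heavy-atom molecule rivals the largest
chemically attainable pair product. Per-bin geometric signals are therefore
intrinsically weak for large molecules at the 0.1 Å grid/B = 100 kernel,
which bounds how sharply a vote-aggregating ensemble can read the 3D half of
the planted rule at n = 200; the recovery experiment is accordingly assessed
over five replicate libraries (replicate-mean OOB Q; replicate-mean
importance ranking).

## Numerical and reproducibility notes

All stochastic stages (generation, embedding, bootstraps, permutation
importance, splits) take explicit integer seeds and are bit-reproducible at
a fixed seed; library generation at a fixed config is byte-identical down to
the SDF output. Problem sizes used by the shipped verification scripts —
200-molecule libraries, 500-tree forests, five replicate seeds — were chosen
as the smallest sizes at which the recovery statistics stabilize.
Eigenvalues use `numpy.linalg.eigvalsh`; shortest paths use networkx BFS;
degenerate inputs (single atoms, missing pairs at a lag, zero variance,
single-class clusters) produce flagged missing/undefined values rather than
exceptions wherever a downstream policy exists.
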