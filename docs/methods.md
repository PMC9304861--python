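# Methods

## Scope and model

`bfuscan` operationalises a rule-based description of the Bfu family of
electron-bifurcating enzymes: a conserved BfuBC core (FMN + B1–B5 + C1)
whose presence is read from sequence, a BfuA inlet subunit whose FeS
cluster profile determines the electron entry path, and a gene-neighborhood
context that determines the functional class (the third substrate).  The
package has three layers: deterministic classification rules, a distance
phylogeny with threshold clades, and a discrete-state mechanism simulator.
None of the layers fit free parameters to data; all constants are packaged
and recorded in output provenance.

## Reference frame and cofactor calling

All subunits are placed in the *A. mobile* NiFe-Bfu numbering frame by
global pairwise alignment (BLOSUM62, affine gaps −11/−1, Biopython
`PairwiseAligner`).  Only the B2 cluster ligands (C438, C476 or T476, H525,
C531, C536) and the FMN-site residues (F182, A202, M204) are experimentally
assigned positions in this frame; ligand positions for A1–A5, B1, B3–B5 and
C1 are **synthetic defaults** (canonical Cys quartets at fixed positions,
with the B1 motif deliberately interleaved inside the B2 span).  They are
packaged so that scanner and data generator share one frame, and they are
user-replaceable through `cofactor_scan.ReferenceFrame` when real
coordinates are available.

A cluster is called *present* when ≥ 0.75 of its ligand positions map to an
allowed residue, *absent* at zero matches, *partial* otherwise.  The 0.75
default tolerates one mismapped ligand in a quartet without ever promoting
a fully ablated cluster; it is a packaged rule, not a fitted value.  The
core verdict requires B2–B5, C1 and His525 — the signature absent from
non-bifurcating Nqo-like homologs.  Entry-cluster priority is A4-first with
an A3 fallback, encoding the Type 1/2 default and the Tsib-style exception
(BfuA lacking the A4 ligands must feed through A3).

## Neighborhood matching and the type decision table

Clusters are the ±10 genes around a BfuB anchor (the largest packaged
operon, the 14-gene Nuo layout, fits with margin); strand is ignored for
ordering.  Signature matching uses four priority bands — composite
(FdhFeFe) > subunit-count-heavy (Nuo, Mbh, Bam, Por, Codh, NiFe, Wor) >
fused-domain (FeFe, Nfn, F420, Fdh) > the BfuA-less Rub arrangement
(rubrerythrin gene directly downstream of bfuB) — with more matched roles
winning within a band and residual ties reported as `Unknown` with a tie
note rather than silently resolved.  Subunit-family signatures require at
least half of the family's roles so that partial annotations still match;
role labels resolve through a configurable vocabulary, letting real product
annotations map onto the controlled roles the generator emits directly.

The type decision table is total: a broken core always wins
(NonBifurcating); a missing BfuA gives T4 only with a recognised
direct-feeding partner, otherwise Unclassified (deliberately cautious — a
BfuA homolog encoded elsewhere in the genome is flagged in the output note,
never rescued).  A5 plays no role in the T2/T3 split; A3 presence is the
operative contrast.  Holoenzyme listings exclude maturation/regulatory
genes (hisK/hydD-style) even when inside the operon.

## Phylogeny

Pairwise distances are 1 − identity over aligned (non-gap) columns of the
same global alignment used for scanning; trees come from a self-implemented
neighbor joining with negative branch estimates clamped to zero and ties
broken toward the lexicographically smallest representative pair, so leaf
order never affects the topology.  This deliberately replaces an ML
pipeline: the downstream computation needs only branch lengths.  Clades are
the leaf-containing components after deleting every edge ≥ 0.33 — the one
reading of a "branch root length < 0.33" clade definition that yields a
well-defined partition; singletons are orphans, and an optional outgroup
leaf is excluded from counting.  NJ consistency is tested against randomly
generated additive matrices and the partition against a graph-components
oracle (networkx).

## Thermodynamics

The couple table stores standard (pH 7) potentials for the twelve
third-reaction configurations plus the NAD, NADP and Fd carrier couples
with physiological values (−280, −380, −500 mV).  Categories are anchored
at the carrier standard potentials: high > −320 mV, mid −420…−320 mV,
low < −420 mV — the only bounds consistent with every tabulated row.  The
Bam row (−620 mV) and the in-text benzoyl-CoA value (−622 mV) are both
packaged, the 2 mV discrepancy preserved.  FdhFeFe has no dedicated row
and maps onto the formate couple, formate being its operative third
reaction.  Energetics use ΔG = −n·F·(E_acc − E_don), n = 2 per leg,
F = 96.485 kJ·mol⁻¹·V⁻¹, Fd as a two-electron carrier; the net is the
exact leg sum.  Signs follow the bifurcating direction (third substrate as
donor), so classes that physiologically run in reverse (e.g. Rub, where
H₂O₂ is the acceptor) show large positive nets in this direction.  Assay
conversion is plain Beer–Lambert dimensional analysis; physiological
potentials are only packaged where stated (none for H₂O₂, F420, MQ or the
low-potential substrates).

## Mechanism simulator

The ten-state cycle is a pure state machine — the proposal names states,
not rates, so no kinetics are modelled.  Conventions chosen where the
narrative leaves freedom: electrons load in the order B1 → FMN(SQ) → C1 →
B5; NAD⁺ binding and the conformational change are fused into one atomic
event (binding is taken as the main driver of the change); the
low-potential pair forms on C1+B2 by relocating the B5 electron in a
separate internal event; ferredoxin is reduced by both electrons in one
event, legal only in the closed conformation (C1–B2 at 13 Å; 19 Å open);
NADH release and relaxation to the open resting state are fused.  Protons
are bookkeeping only: +2 per H₂ oxidised, −1 per NAD⁺ reduced, netting the
+3 H⁺ of the overall stoichiometry.  Every event has an exact inverse and
the legality table is closed under inversion, so the confurcating direction
is the same machine run backwards.  Inversion restores the enzyme
configuration and all *net* tallies; the gross H₂ counters are monotone
turnover counts (one H₂ oxidised and re-made is one consumed plus one
produced, not zero of each).  Conservation — core electron count equals the
summed substrate electron flow — and NAD-gating of Fd_red release are
verified by exhaustive enumeration of all legal paths up to 12 events.

## Synthetic data

The generator emulates the family's discovery setting at desk scale:
fifteen operon templates covering all four types and thirteen classes
(three Fdh configurations — fused, A3-less, A3-containing — all map to
class Fdh), with InterPro-style architectures, planted ligand motifs (Thr
at 476 for the FeFe-type templates), neutral decoy genes, optional
standalone catalytic cassettes placed ≥ 20 genes from any bfuB (to probe
the window), and optional Nqo-like decoys with B2–B5 ablated.  Divergence
is i.i.d. substitution, uniform over the 19 alternatives, exempting
ligand/signature positions unless ablated; there are no indels, so every
planted subunit keeps exact register with the reference frame — one reason
the noiseless-recovery results say nothing about alignment robustness on
real, indel-containing sequences.  Gene lengths for non-Bfu roles are drawn
from broad ranges (200–600 residues) rather than exact counts; no rule
depends on exact lengths.

Cohorts seed each template from a distinct ancestor (the reference mutated
at a `between_divergence` rate, allowed up to 1.0 = full randomisation of
unprotected sites) and diverge copies at a within-template rate.  The
substitution-only model bounds the achievable pairwise p-distance: two
ancestors mutated at rate 0.45 saturate near 0.69, which places NJ stem
edges below the fixed 0.33 cut.  The *designed* clade-recovery cohort
therefore uses within = 0.02 and between = 0.9 (stems ≈ 0.40), chosen from
this geometry; the default cohort keeps 0.05/0.45 for classification
exercises where clade separation is not at stake.  No within-clade
divergence scale exists for the real dataset, so the 0.33 threshold's
empirical meaning cannot be calibrated synthetically — clade-recovery
results demonstrate internal consistency, not field performance.

## Determinism and problem sizes

All randomness flows from integer seeds through `numpy` generators; reruns
with the same config are byte-identical (verified by output hashing).  Test
and acceptance problem sizes — 15-genome noiseless cohorts, 9–12-leaf
designed cohorts, 200 random trees/matrices, alignment oracles at lengths
≤ 12, exhaustive mechanism paths ≤ 12 events — were chosen so each property
is checked exhaustively or at saturation while the full suite stays quick
on one CPU.

## Known limitations

Real metagenome flags are metadata, never inferred.  Domain evidence is an
input: no HMM search or InterProScan invocation.  The A-cluster ligand
defaults are synthetic; cluster calls on real BfuA sequences require
supplying real positions.  The Bam class is reported as T2 even though its
BfuBC module feeds a second bifurcating module rather than the terminal
substrate reduction — the entry semantics of that cascade are noted, not
modelled.  The mechanism simulator encodes a hypothesis's narrative, not
physics: no flavin potential crossing, no free-energy landscape, no rates.
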