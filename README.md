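# transpt

Product chain-length prediction for *trans*-prenyltransferases (*trans*-PTs),
the enzymes that condense C5 isoprene units (IPP onto an allylic diphosphate)
into the linear polyprenyl pyrophosphates — FPP (C15), GGPP (C20), GFPP (C25)
and longer (≥C30) — that feed terpenoid biosynthesis. Databases are full of
*trans*-PT genes annotated only by similarity; which precursor an enzyme
actually makes determines which terpenoids a species can produce, and is
what this package predicts from sequence alone. Intended users are people
mining genomes for specific precursor synthases (for example C25-producing
GFPPSs, the gateway to sesterterpenes) and people studying chain-length
determination itself.

## The model

Product length in a *trans*-PT is set by an elongation tunnel lined by three
tiers ("floors") of residues on helices D, E and F, one α-helix pitch
(~5.4 Å ≈ one C5 unit) apart. A growing chain passes a floor when the
side chains there are small, and is terminated when they are bulky: blocking
at floor 1, 2 or 3 yields FPP, GGPP or GFPP respectively, and an open tunnel
yields ≥C30 products.

The predictor makes this quantitative:

1. **Template search.** The query is globally aligned (Needleman–Wunsch,
   affine gaps, BLOSUM62, 11/1) against eleven reference templates; the one
   with the highest percent identity is selected.
2. **Floor mapping.** The template's nine annotated floor positions
   (3 floors × 3 sites) are projected through the alignment onto the query.
3. **Scoring and cascade.** Each residue *r* has a blocking score *B(r)* ∈
   [0, 1] (normalised side-chain volume, discounted for torsionally flexible
   chains). The floor score is the weighted sum
   *S<sub>f</sub>* = Σ<sub>s</sub> *w<sub>f,s</sub>* · *B*(*r<sub>f,s</sub>*)
   with Σ<sub>s</sub> *w<sub>f,s</sub>* = 1, and the call cascades top-down:
   *S*₁ > θ₁ → C15; else *S*₂ > θ₂ → C20; else *S*₃ > θ₃ → C25; else ≥C30.
   A decisive score within 5% of its threshold produces a dual call such as
   `C20/C25`.

Weights and thresholds can be refitted from labeled data by exhaustive
simplex-grid search with per-floor threshold sweeps (`transpt train`), and
the package ships a synthetic-fixture generator so the whole pipeline is
testable offline.

**Note:** the bundled template registry is a *synthetic stand-in* — eleven
deterministic fixture sequences keyed by the PDB ids of the curated
reference enzymes, with floor annotations consistent with each template's
native product. Swap in a curated registry file (`--registry`) for real
screening work.

## Worked example

The published diagnostic case: an enzyme whose mapped first-floor residues
are Ala/Thr/Ile (small — the chain passes) and second-floor residues
Leu/Phe/Met (bulky — the chain terminates):

```python
from transpt import FloorAssignment, default_model, predict_from_assignment

assignment = FloorAssignment.from_residues(
    ("Ala", "Thr", "Ile"), ("Leu", "Phe", "Met"), ("Gly", "Gly", "Gly"))
pred = predict_from_assignment(assignment, default_model())
print(pred.primary, [round(s, 4) for s in pred.floor_scores])
```

prints

```
C20 [0.2562, 0.6611, 0.0]
```

Floor 1 scores 0.256 (below the 0.40 threshold, passable), floor 2 scores
0.661 (blocked): the product is GGPP, C20.

End-to-end on the command line — simulate a labeled variant set, predict,
and score the predictions:

```
$ transpt simulate --per-class 2 --seed 3 --out-prefix demo
wrote 8 records to demo.fasta / demo.tsv
$ transpt predict demo.fasta --out demo_report.tsv
$ transpt evaluate --report demo_report.tsv --labels demo.tsv
overall accuracy: 100% (8/8)
within one C5 unit: 100% (8/8)
mean best-template identity: 95.2%
...
```

The report TSV carries, per query: best template, percent identity, the
nine mapped floor residues with positions, the three floor scores, the
predicted class(es) and confidence flags.

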