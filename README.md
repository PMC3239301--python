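# silverner

Silver-standard corpus harmonisation and evaluation for multi-annotator
biomedical named-entity recognition.

## The problem

Gold-standard NER corpora are manually curated, expensive, and therefore
small. An alternative at scale is a **silver standard corpus (SSC)**: run
several independent annotation systems over one large shared corpus and
automatically merge ("harmonise") their typed entity mentions, keeping only
the spans the systems agree on. `silverner` implements that harmonisation
and the matching machinery needed to evaluate any annotated corpus against
a reference. It targets the four coarse biomedical semantic groups —
chemicals/drugs (CHED), genes/proteins (PRGE), diseases/disorders (DISO)
and species (SPE) — with an explicit registry for extensions.

## The method

Annotations are compared per sentence and per semantic group. For two spans
*a*, *b* with token sets inside their extents, each token *t* is weighted
`tf(t) · idf(t)` with `idf(t) = ln(N / df(t))` counted at document level
over the whole shared corpus. The pair **aligns** when their token extents
overlap and

```
cos(a, b) = ⟨va, vb⟩ / (‖va‖ ‖vb‖) > τ        (default τ = 0.98)
```

Because tokens occurring in every document have weight 0, boundary
disagreements over low-content words (determiners, prepositions) never
affect the score — that is what makes a threshold as strict as 0.98 usable.
Clusters are the connected components of the pairwise alignment graph; a
cluster is accepted when at least *v* **distinct sources** contributed to
it (*n*-vote agreement, default v = 2), and the consensus takes the
boundaries of the shortest member. Evaluation supports **exact**, **nested**
(containment either way) and **cosine** matching (τ = 0.98 / 0.9 presets),
with one-to-one maximum matching for TP counting and macro-averaged
precision / recall / F over groups.

A synthetic module generates ground-truth corpora and simulates imperfect
annotators with the disagreement phenomena seen between real systems:
missed mentions, spurious mentions, one-token boundary jitter, tag
confusion between CHED and PRGE (the "insulin" case), and inflectional
boundary variants ("tumour" vs "tumours").

## Worked example

```python
import silverner as sn

spec = sn.TruthSpec(n_documents=100, seed=42)
profiles = [
    sn.AnnotatorProfile(source=f"p{i}", miss_rate=0.1, spurious_rate=0.2,
                        boundary_jitter=0.1, seed=42_000 + i)
    for i in range(4)
]
rec = sn.recovery_experiment(spec, profiles,
                             sn.HarmonisationConfig(tau=0.98, votes=2))

print(f"truth mentions:  {len(rec.truth.annotations)}")
print(f"silver mentions: {len(rec.silver.annotations)}")
for mode in ("exact", "nested", "cos0.98", "cos0.9"):
    cell = rec.silver_vs_truth.get("avg", mode)
    print(f"silver vs truth  {mode:8s} P={cell.precision:.3f} "
          f"R={cell.recall:.3f} F={cell.f_measure:.3f}")
print(f"mean annotator F (cos 0.98): {rec.mean_annotator_f('cos0.98'):.3f}")
print(f"consensus gain:              {rec.consensus_gain('cos0.98'):.3f}")
```

prints

```
truth mentions:  1050
silver mentions: 1054
silver vs truth  exact    P=0.979 R=0.983 F=0.981
silver vs truth  nested   P=0.986 R=0.990 F=0.988
silver vs truth  cos0.98  P=0.979 R=0.983 F=0.981
silver vs truth  cos0.9   P=0.981 R=0.985 F=0.983
mean annotator F (cos 0.98): 0.816
consensus gain:              0.165
```

Each of the four simulated annotators misses 10 % of true mentions, jitters
10 % of boundaries by one token and adds 0.2 spurious mentions per sentence;
individually they reach F ≈ 0.82 against the truth. The 2-vote consensus
reaches F ≈ 0.98: independent errors rarely agree, so voting filters
spurious mentions, and shortest-boundary consensus repairs jittered spans.
The vote sweep in `rec.sweep_vs_truth` shows the precision/recall trade-off
— raising *v* pushes precision toward 1 while recall falls — which is why a
middle vote threshold gives the best F balance.

## Command line

```sh
silverner simulate  --spec spec.yaml --seed 3 --out corpora/   # truth + K annotators
silverner idf       --corpus corpora/truth.xml --out idf.tsv
silverner harmonise corpora/p0.xml corpora/p1.xml corpora/p2.xml \
                    --tau 0.98 --votes 2 --out silver.xml --stats-out stats.tsv
silverner evaluate  --pred silver.xml --ref corpora/truth.xml \
                    --modes exact,nested,cos0.98,cos0.9 --report report.tsv
silverner convert   silver.xml --to standoff --out silver_standoff/
```

Corpora travel either as a minimal inline XML dialect
(`<corpus><doc><s>… <e grp="PRGE" ids="P01308" src="p0">insulin</e> …`) or
as standoff (sentence-per-line text plus an annotation TSV); both round-trip
losslessly and writes are canonical, so repeated runs are byte-identical.
Every command writes a `*.config.yaml` sidecar with its materialised
settings.

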