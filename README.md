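# dpnkit — Drug Prescription Networks from ATC-coded dispensation records

`dpnkit` builds and analyses **Drug Prescription Networks (DPNs)** from
patient-level drug dispensation records, for pharmacoepidemiologists and
health-services researchers working with administrative claims data.

In a DPN, every drug observed in a cohort is a node and two drugs are
joined by an edge when at least one patient received both during the
observation window. Drugs are identified by WHO **ATC** codes, whose
five nested levels (anatomical group `J` → substance `J01CR02`) yield
five networks of increasing resolution from one dataset. Node *i*
carries the patient count *Pᵢ* (patients prescribed drug *i*) and edge
*i–j* carries *C<sub>ij</sub>* (patients prescribed both), so the graph
is a compact summary of co-prescription in the cohort.

The toolkit covers the full workflow:

- **Ingest** — delimited records (patient id, sex, birth year, date,
  ATC level-5 code), with explicit exclusion of incomplete/ambiguous
  rows and a birth-year inclusion window, plus demography tables.
- **Networks** — DPNs at all five ATC levels, GraphML / edge-list CSV
  interchange, isolated nodes preserved.
- **Metric panel** — density *d* = 2E/(N(N−1)), degree / betweenness /
  closeness with means and CV%, Newman degree assortativity *r*, and
  the random-graph giant-component criteria (k̄ > 1, k̄ > ln N).
- **φ thresholding** — for each edge the binary-variable Pearson
  correlation

  φ<sub>ij</sub> = (n·C<sub>ij</sub> − Pᵢ·P<sub>j</sub>) / √(Pᵢ(n−Pᵢ)·P<sub>j</sub>(n−P<sub>j</sub>)),

  retention curves of connected nodes and edges over a φ\* grid,
  logistic fits on log₁₀ φ\*, and **φmax** — the threshold maximising
  the gap between the node and edge curves, used to prune "weak" edges
  while keeping the network connected.
- **Stratified comparison** — sex × age layers over a common node
  universe, Euclidean distances between binary neighbourhood profiles,
  ward.D2 dendrograms and cluster extraction.
- **Simulator** — synthetic cohorts with realistic sex/age structure,
  Zipf-like drug popularity and planted co-prescription modules, so
  every stage is testable without access to confidential claims data.

## Worked example

```python
from dpnkit import (SimConfig, generate_records, build_incidence,
                    build_dpn, summary, analyse)

records = generate_records(SimConfig(n_patients=4000, seed=1))
dpn1 = build_dpn(build_incidence(records, level=1))   # anatomical groups
s = summary(dpn1, weighting="unweighted")
print(s.N, s.E, round(s.d, 3), round(s.k_mean, 3), s.r)
# 14 91 1.0 13.0 None

dpn3 = build_dpn(build_incidence(records, level=3))
curve = analyse(dpn3)                                  # φ retention analysis
print(dpn3.N, dpn3.E, round(curve.phi_max, 3))
# 776 26315 0.095
```

At level 1 the 14 anatomical groups form a *complete* graph (density
1.000, every degree 13), so assortativity is not applicable (`None`) —
co-prescription across broad drug classes is essentially universal in a
dense cohort. At level 3 the network is much larger and sparser, and
thresholding its edges at φ\* = φmax ≈ 0.095 strips the
weak-association edges while most nodes stay connected.

The same pipeline runs from the shell:

```bash
dpnkit simulate --n-patients 4000 --seed 1 --out records.csv
dpnkit build records.csv --level 3 --out dpn3.graphml
dpnkit metrics dpn3.graphml --weighting cij
dpnkit phi dpn3.graphml --out-prefix phi3
dpnkit run-all --config run.yaml          # full multi-level pipeline
```

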