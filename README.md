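# kanokit

Kano-model needs assessment from paired-Likert surveys: attribute
classification, better–worse coefficient analysis, sensitivity-based
priority ranking, and questionnaire reliability diagnostics.

## Who this is for

Survey researchers in public health, nursing and service-quality studies
who run Kano questionnaires: each of *k* service items is asked twice —
a **functional** question ("how would you feel if this service were
provided?") and a **dysfunctional** question ("… if it were not?") — both
answered on a five-level scale coded 1 = *Like*, 2 = *Take it for
granted*, 3 = *Indifferent*, 4 = *Reluctant*, 5 = *Dislike*. The shipped
default instrument is a 43-item mutual-aid older-care needs questionnaire
(five dimensions: safety/health, daily life, learning/social, spiritual,
entertainment) with its published attribute and coefficient table packaged
as a fixture.

## The method

1. **Classification.** Each (functional, dysfunctional) answer pair maps
   through the fixed 5×5 Kano evaluation matrix to one of six categories:
   must-be (M), one-dimensional (O), attractive (A), indifferent (I),
   reverse (R), questionable (Q). An item's attribute is the modal
   category over respondents (ties break M > O > A > I > R > Q and are
   flagged).
2. **Coefficients.** Per item, with category counts A, O, M, I (R and Q
   excluded from both sides):

   Better / SI = (A + O) / (A + O + M + I)
   Worse / DSI = −(O + M) / (A + O + M + I)

3. **Sensitivity and screening.** R = √(Better² + Worse²) ranks
   improvement urgency. In the SI–|DSI| plane, quarter-circle arcs at
   radius 0.707 (element line) and 1.061 (key-element line) partition items
   into *deferred*, *element* and *key* zones; the signed radial distance
   R − 1.061 is reported per item.
4. **Reliability.** Cronbach's α, the KMO measure of sampling adequacy
   (via anti-image partial correlations), and Bartlett's test of
   sphericity, from their closed forms.

A seeded synthetic-panel generator inverts the evaluation matrix: each
item carries a designed attribute, noise-free respondents answer from the
matrix cells consistent with it, and a per-pair corruption rate replaces
codes with uniform draws — so the full pipeline is testable without raw
survey data.

## Worked example

Regenerate the published priority ranking from the packaged coefficient
table:

```bash
$ kanokit run --from-fixture --out out/
pipeline complete: 43 items -> out/
```

The top of `out/priority.json`:

```
{'rank': 1, 'item_id': 'A1', 'label': 'Exercise',                  'attribute': 'O', 'sensitivity_pct': 96.7,  'zone': 'element'}
{'rank': 2, 'item_id': 'B4', 'label': 'Travelling',                'attribute': 'O', 'sensitivity_pct': 96.5,  'zone': 'element'}
{'rank': 3, 'item_id': 'B3', 'label': 'Hair cutting',              'attribute': 'O', 'sensitivity_pct': 93.91, 'zone': 'element'}
{'rank': 4, 'item_id': 'D2', 'label': 'Psychological counselling', 'attribute': 'O', 'sensitivity_pct': 91.48, 'zone': 'element'}
{'rank': 5, 'item_id': 'A6', 'label': 'Boiling traditional Chinese medicine', 'attribute': 'O', 'sensitivity_pct': 86.69, 'zone': 'element'}
census: {'M': 17, 'O': 7, 'A': 10, 'I': 9}
```

Reading: exercise is the most urgent improvement target (sensitivity
96.70%), and the instrument splits into 17 must-be, 7 one-dimensional,
10 attractive and 9 indifferent items. Sample-size guidance for a new
study with this instrument:

```bash
$ kanokit design --items 43
items: 43
minimum sample size (5 per item): 43 x 5 = 215
maximum sample size (10 per item): 43 x 10 = 430
```

Or in Python, end to end on a synthetic panel:

```python
import kanokit as kk

fx = kk.load_table4_fixture()
items = tuple((i, kk.KanoCategory(a)) for i, a in fx["attribute"].items())
panel = kk.simulate_panel(kk.SimulationConfig(240, items, noise_rate=0.1, seed=7))

clf = kk.KanoClassifier().fit(panel)           # per-item tallies + attributes
ranked = kk.KanoPrioritizer().fit(clf.tally_frame_).results_
print(ranked[["sensitivity", "rank", "zone"]].head())
```

Both estimators follow the scikit-learn protocol (`fit`, `get_params`,
fitted attributes with trailing underscores) and accept/return pandas
objects.

## Layout

- `src/kanokit/core.py` — evaluation matrix, tallies, `KanoClassifier`
- `src/kanokit/scoring.py` — coefficients, sensitivity, arcs, `KanoPrioritizer`
- `src/kanokit/reliability.py` — α / KMO / Bartlett, `ReliabilityDiagnostics`
- `src/kanokit/simulate.py` — seeded synthetic panel generator
- `src/kanokit/io.py`, `pipeline.py`, `plotting.py`, `cli.py` — formats,
  orchestration, figures, command line
- `docs/methods.md` — model details, assumptions and limitations
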