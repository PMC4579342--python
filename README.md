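# rfaligner

Joint alignment of shallow-sequenced **read clouds** (synthetic long-read /
linked-read wells), built to place short reads confidently *inside*
segmental duplications and other high-identity repeats.

In a read-cloud protocol, long (~10 kb) DNA fragments are diluted into
barcoded wells — each well holding ~1–2% of the genome — and sequenced
shallowly with short reads (`C_R ≤ 2×` per fragment, `C = C_F × C_R` total
depth). All reads sharing a well that cluster in genome coordinates came
from one hidden long fragment. A single 100-bp read inside a 98%-identity
duplication cannot tell the copies apart; its cloud, spanning thousands of
bases, can.

rfaligner models each well's hidden fragments `M_c = (L_c, X_c, λ_c, B_c,
S_c, E_c)` as a Markov Random Field in which every candidate molecule
induces one potential over the reads assigned to it,

    P(R) ∝ ∏_c φ_c(R_c),   φ_c(R_c) = Σ_{M_c} P(M_c) P(R_c | M_c),

and finds the joint MAP assignment `r* = argmax_r Σ_M P(R = r | M) P(M)`
of every read in the well at once. The hidden fragment sequence `X_c` is
eliminated column-by-column and the read density `λ_c` by quadrature, so a
potential costs time linear in aligned bases. After convergence the package
computes calibrated confidence: per-read posteriors (emitted as Phred MAPQ,
with the conventional MAPQ ≥ 10 ⇔ ≥ 90% confidence filter), per-cloud
quality scores, molecule-existence posteriors, and end-marker based
detection of fragment collisions.

The package ships:

* `cloud_seeding` — pass-1 cloud detection (3.5-kb single-linkage clusters,
  ≥ 6 reads), end-marker splitting, the per-well *abbreviated reference*
  (one contig per candidate fragment) and pass-2 candidate domains (≤ 15
  placements per read);
* `prior_model` — the learned protocol prior `P(M)`: existence probability,
  end-marker table `P(B)`, and a 2-D kernel density estimate of
  `(log S, log λ)` per marker state, serialisable to JSON;
* `rfa_mrf` — the potential engine (incremental variable elimination) and
  restarted ICM + block-move MAP search;
* `quality` — MAPQ, cloud quality, existence posteriors, collision filter;
* `simulator` — repeat genomes and stencil-based read-cloud wells with full
  ground truth and a first-order base-quality/error model;
* `harness` — a built-in exact mini multi-mapper for desk-scale references
  and the Baseline / Naive / RFA / Oracle evaluation;
* a CLI: `rfaligner simulate | train-prior | align-well | evaluate |
  end-to-end`.

See `docs/methods.md` for the model, its assumptions and the numerical
choices.

## Worked example

Simulate a 1-Mb genome carrying four duplication pairs at 98–99% identity,
learn the prior from 20 wells, align 10 wells, and compare selectors:

```python
import pandas as pd
from rfaligner.simulator import SimConfig, make_repeat_genome, simulate_well
from rfaligner.harness import (KmerIndex, WellConfig, run_well, train_prior,
                               method_tables, evaluate)

cfg = SimConfig(genome_length=1_000_000, n_duplications=4,
                dup_length_range=(8000, 12000), identity_range=(0.98, 0.99),
                well_fraction=0.05, seed=7)
genome, dups = make_repeat_genome(cfg)
index = KmerIndex(genome)
training = [simulate_well(genome, cfg, seed=1000 + w, well_id=w)[0]
            for w in range(20)]
prior = train_prior(training, genome, index=index)
print(f"p_exist={prior.p_exist:.2f}  marker_eff={prior.marker_eff:.2f}  "
      f"mean fragment={prior.fragment_size_mean():.0f} bp")

tables = {m: [] for m in ("baseline", "naive", "rfa", "oracle")}
parts = []
for w in range(10):
    reads, _ = simulate_well(genome, cfg, seed=w + 1, well_id=w)
    truth = pd.DataFrame([vars(r.truth) for r in reads])
    parts.append(truth)
    res = run_well(reads, genome, prior, WellConfig(seed=0), index=index,
                   well_id=w)
    for m, t in method_tables(reads, res, truth).items():
        tables[m].append(t)
truth = pd.concat(parts, ignore_index=True)
tables = {m: pd.concat(ts, ignore_index=True) for m, ts in tables.items()}
report = evaluate(tables, truth)
print(report.aggregate[["n_multimapped", "frac_conf_correct_multi",
                        "wrong_rate_conf_multi"]].round(3).to_string())
```

Output:

```
p_exist=0.39  marker_eff=0.74  mean fragment=10401 bp
          n_multimapped  frac_conf_correct_multi  wrong_rate_conf_multi
method
baseline            389                    0.237                    0.0
naive               389                    0.237                    0.0
rfa                 389                    1.000                    0.0
oracle              389                    1.000                    0.0
```

Reading it: the prior learner recovered the simulated protocol (end-marker
efficiency 0.77 was simulated, 0.74 estimated; fragment mean ~10 kb), and
of the 389 reads that were *multimapped* in the abbreviated reference —
reads a conventional aligner must leave at MAPQ ≈ 0, which is why Baseline
and Naive retain only 24% of them after the MAPQ ≥ 10 filter — RFA placed
every one confidently and correctly, matching the Oracle upper bound, with
a 0% wrong-placement rate among its confident calls.

The same flow is available from the shell:

```bash
rfaligner simulate --seed 1 --wells 10 --out simdir
rfaligner evaluate --simdir simdir --out report.json
```

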