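# ldlrscreen

Hit-calling funnel for arrayed genome-wide RNAi screens of LDL-receptor
(LDLR) activity, read out as per-well fluorescent LDL (DiI-LDL) uptake, with
integration of a matched sterol-perturbation expression experiment.

The package is for screening analysts who have per-well measurement tables
(plate, well, replicate, gene, viable-cell count, mean intensity) and want
the complete, reproducible decision chain from raw wells to validated
candidate regulators — plus a synthetic screen generator with known ground
truth to calibrate and stress-test every rule in that chain.

## The method

For well intensity $x$ on plate $p$, after excluding wells with fewer than
500 segmented nuclei (cytotoxic knockdowns), the robust z-score is

$$z = \frac{x - \mathrm{median}_p}{c \cdot \mathrm{MAD}_p}$$

with median and MAD taken over all QC-passing wells of the plate (including
the randomly distributed non-silencing controls) and $c = 1$ by default, so
one z unit is literally one plate MAD. The decision rules are:

- **Primary hit** — at least 2 of 3 replicate wells with $z \ge 2.0$ (up)
  or $z \le -2.0$ (down), inclusive, same direction; genes are ranked by
  mean replicate z.
- **Candidate** — a primary hit whose expression is cholesterol-modulated
  (two-sided pooled t-test, $P \le 0.05$, signed fold-change $\ge +1.1$
  under statin / $\le -1.1$ under native LDL, duplicates per condition)
  and/or that carries a lipid-GWAS association flag.
- **Validated** — at least 1 of the pool's 3 individual siRNAs reproduces
  the primary direction at $|z| \ge 1.6$ (inclusive) in the deconvolution
  rescreen.

The signed fold-change convention maps a ratio $r$ of group means to $r$
when $r \ge 1$ and $-1/r$ otherwise, so no value falls in $(-1, 1)$.

## Worked example

```python
from ldlrscreen import SimulationConfig, run_simulated_screen

run = run_simulated_screen(SimulationConfig(n_genes=300, seed=3))
print(run.report.to_text())
```

```
Screening funnel
----------------
genes screened      300
scorable            295
primary hits        18 (up 9, down 9)
candidates          6
rescreened          6
validated           4
validation rate     66.7%
```

Of 300 simulated genes (12 true regulators spiked in), 295 were scorable —
the rest lost too many replicate wells to the 500-cell viability filter.
The replicate z-rule called 18 primary hits (all 12 true regulators plus 6
null genes that cleared 2 MADs twice by chance), 6 of which carried
expression or GWAS support and entered the deconvolution rescreen, where 4
validated. The same stages are available as subcommands of the `ldlr-screen`
CLI (`simulate`, `normalize`, `call-hits`, `de`, `integrate`, `deconvolve`,
`report`, `evaluate`), exchanging delimited-text tables in an output
directory.

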