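# zahnreihen

Quantitative analysis of tooth replacement in polyphyodont (continuously
tooth-replacing) reptiles, built for vertebrate palaeontologists working from
CT-derived dentition measurements. The package covers four connected
analyses on the example of the early-diverging ornithopod dinosaur
*Jeholosaurus shangyuanensis*:

1. **Replacement waves (Zahnreihen) and Z-spacing.** Each replacement tooth
   gets a replacement index `RI = ℓ_r / ℓ_f` (replacement crown length over
   the functional tooth's length at the same alveolus); the functional tooth
   carries `1 + max RI` (or exactly 1.0 with no successor). Plotted against
   tooth position, indices fall in degressive sequences — Zahnreihen — and
   the horizontal offset between successive sequences, the **Z-spacing Z**
   (in tooth positions), summarises the wave: `Z > 2` means replacement
   sweeps rostral→caudal, `Z = 2` strict odd/even alternation, `Z < 2` a
   reversed wave.
2. **Odontochronology.** Incremental lines of von Ebner are daily dentine
   couplets: their count is the tooth formation time in days; their mean
   width is the daily dentine apposition rate (DDAR, µm/day). For a newly
   erupted tooth whose family holds no successor, the formation time is an
   upper bound on the replacement interval; with two sectioned generations
   of one family, the rate is the difference of their increment counts.
3. **Ontogeny.** Per-specimen counts of alveoli, functional and replacement
   teeth (by generation) and resorbed-tooth remnants, replacement:functional
   ratios, and monotonicity verdicts along a growth series ordered by stage
   and skull length.
4. **Ancestral-state reconstruction.** A topology is time-calibrated from
   first-appearance dates by the 'equal' method; the replacement-pattern
   character (one / two / three-plus replacement generations) is fitted with
   the Mk model under ER, SYM and ARD rate matrices by maximum likelihood
   (Felsenstein pruning); stochastic character maps are sampled in
   proportion to the models' Akaike weights `w_m = exp(−Δ_m/2)/Σ exp(−Δ/2)`,
   and per-node state frequencies across the maps estimate ancestral states.

Every stage has a ground-truthed synthetic generator (`zahnreihen.simulate`)
so the whole pipeline is verifiable without fossil material.

## Worked example

Recover a known replacement-wave period from a noisy synthetic dentition
(`examples/01_zspacing_from_synthetic_dentition.py`):

```python
from zahnreihen import analyze_row
from zahnreihen.simulate import DentitionSimSpec, simulate_dentition

spec = DentitionSimSpec(n_positions=16, period=2.5, noise_cv=0.03, seed=42)
specimen, provenance = simulate_dentition(spec)
result = analyze_row(specimen.row("maxilla", "left"))
```

prints

```
generating period (true Z-spacing): 2.5
recovered mean Z-spacing:           2.5
number of Zahnreihen:               8
spacing measurements:               21
inferred wave direction:            rostral_to_caudal
```

The generator laid down a replacement wave that advances 2.5 tooth positions
per wave; segmentation found 8 Zahnreihen across the 32 plotted teeth, and
the mean of the 21 polyline-to-polyline distances recovered the period. A
mean above 2.0 classifies the wave as rostral→caudal.

Summarising the published per-side Z-spacing table of the six known
*Jeholosaurus* specimens (`examples/02_published_z_spacing_summary.py`):

```
premaxilla  n= 4 sides  grand mean 2.338  -> rostral_to_caudal
maxilla     n=12 sides  grand mean 2.533  -> rostral_to_caudal
dentary     n=12 sides  grand mean 2.478  -> rostral_to_caudal
```

The other examples cover formation times and rate bounds (46-day maxillary
bound; premaxillary bound rising 25 → 33 days through ontogeny at similar
DDAR), ontogenetic count trends, and a full calibrate→fit→map ancestral-state
run that estimates `one_generation` as the ancestral replacement pattern.

A thin CLI mirrors the library for batch work:

```sh
zahnreihen simulate --out sim/ --period 2.5 --noise-cv 0.03 --seed 1
zahnreihen zahnreihe --input sim/tooth_table.csv --out results/ --seed 1
zahnreihen rates --input increments.csv --out results/
zahnreihen asr --tree tree.nwk --ages ages.csv --chars states.csv --out asr/
```

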