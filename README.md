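# cleavemap

Simulation and analysis of strand-specific DNA cleavage maps for enzymes —
meiotic SPO11 and other topoisomerase-like nucleases — that cut duplex DNA
leaving **2-nt 5′ overhangs** centered on a twofold rotational symmetry axis
(the *dyad axis*). It targets nucleotide-resolution break-mapping experiments
(TDP2-seq / S1-seq style), where the covalently attached protein is removed,
ends are filled in and adaptor-ligated, and each read is assigned to the
nucleotide immediately next to the adaptor.

The package is aimed at people analyzing in-vitro cleavage reconstitutions or
in-vivo break maps who need, without any external data downloads:

- a **synthetic library generator** — reference sequences, sequence-biased
  cleavage events, nick/DSB mixtures, incomplete-fill-in read misassignment,
  and uniform nonspecific background (a catalytically dead control);
- **strand maps** — per-position top/bottom read-count tracks, RPM
  normalization, region masking, 21-bp Hann smoothing for overview profiles;
- an **overhang-polarity test** — the Pearson cross-correlation between the
  strand tracks peaks at lag **+1** when breaks have the expected 2-nt 5′
  overhang geometry (top read at `dyad_left`, bottom read at `dyad_left + 1`);
- **peak calling** as strand-specific RPM-threshold exceedances
  (presets >3,000 / >10 / >15 RPM for plasmid-, bacterial- and yeast-scale
  maps) with a **fill-in artifact filter**: a top-strand candidate at *x* is
  discarded when `top[x] < top[x−1]`, a bottom-strand candidate when
  `bottom[x] < bottom[x+1]`;
- **dyad-frame composition analysis** — reorientation of bottom-strand peaks
  so the adaptor-adjacent base sits at position −1, base-composition matrices,
  GC-corrected sequence logos (per-position information
  `R = Σ_b f_b log₂(f_b/q_b)`, letter height `f_b·R`), a rotational-symmetry
  score testing `f(p, b) = f(−p, complement(b))`, degenerate IUPAC motif
  scanning (e.g. the favored GNATNC signature and its CNTANG control), and
  anchored average profiles;
- **binding and kinetics** — two-independent-site equilibrium occupancy
  `θ = P/(K_d+P)`, dimer occupancy `θ²`, hyperbolic (and ligand-depletion)
  K_d fits, descriptive two-phase association fits
  `Y(t) = A₁(1−e^{−k₁t}) + A₂(1−e^{−k₂t})`, and a mass-action **kinetic-trap
  model** in which cleavable sites assemble a dimer sequentially
  (`S + P ⇌ SP ⇌ SP₂ → cleaved`) while excess decoy monomer sites sequester
  protein — reproducing biphasic utilization curves and order-of-addition
  asymmetry in staged substrate-challenge experiments.

## Worked example

```python
import numpy as np
import cleavemap as cm

ref = cm.generate_reference(10_000, gc=0.5, topology="circular", seed=7)
model = cm.BiasModel.symmetric_gnatnc(favor=10.0, strength=2.0)
prep = cm.LibraryPrepParams(f_partial=0.3, background_rate=0.001)

events = cm.sample_cleavage_events(ref, model, 3000, prep, seed=11)
reads = cm.simulate_library(events, prep, len(ref), ref.topology, seed=12)
smap = cm.build_strand_map(reads, ref)
print(f"reads: {len(reads)}   polarity offset: {cm.polarity_offset(smap):+d}")

rpm = cm.normalize_rpm(smap)
called = cm.call_peaks(rpm, threshold=3000)
kept = cm.top_n_peaks(cm.filter_fillin_artifacts(called, rpm), 50)
print(f"peaks >3000 RPM: {len(called)} called, {len(kept)} kept after artifact filter (top 50)")

windows = [cm.extract_dyad_window(ref, p, halfwidth=3) for p in kept]
comp = cm.composition_matrix(windows)
print(comp.to_frame().round(2))
print(f"symmetry score: {cm.symmetry_score(comp):.4f}")

logo = cm.gc_corrected_logo(comp, background_gc=0.5)
print("information (bits):", np.round(logo.information, 2))

m = cm.OccupancyModel(kd=1.8, p_free=10.0)
print(f"dimer-bound fraction at 10 nM: {100 * cm.fraction_dimer_bound(m):.0f}%")
```

Output:

```
reads: 5980   polarity offset: +1
peaks >3000 RPM: 130 called, 50 kept after artifact filter (top 50)
             A     C     G     T
position
-3        0.00  0.00  1.00  0.00
-2        0.22  0.26  0.20  0.32
-1        1.00  0.00  0.00  0.00
 1        0.00  0.00  0.00  1.00
 2        0.34  0.16  0.28  0.22
 3        0.00  1.00  0.00  0.00
symmetry score: 0.0067
information (bits): [2.   0.02 2.   2.   0.05 2.  ]
dimer-bound fraction at 10 nM: 72%
```

The +1 offset confirms the overhang polarity of the simulated breaks even
though 30% of reads were misassigned by incomplete fill-in; the artifact
filter trims the shifted false peaks (130 → true dyad positions). The
recovered composition shows the embedded, rotationally symmetric signature —
G at −3 / C at +3, A at −1 / T at +1 — with ~2 bits of information at the
determinate positions and a near-zero symmetry score. The last line is the
equilibrium arithmetic for a cleavable site with two independent 1.8 nM
monomer binding sites at 10 nM protein: 72% of substrate carries a full
dimer.

## Command line

Every stage is also exposed through the `cleavemap` command:

```bash
cleavemap simulate --length 10000 --n-events 1000 --bias gnatnc --seed 1 --out-prefix demo
cleavemap map --fasta demo.fasta --reads demo.reads.bed --rpm --out-prefix demo
cleavemap polarity --fasta demo.fasta --reads demo.reads.bed
cleavemap peaks --fasta demo.fasta --reads demo.reads.bed --threshold 3000 --out peaks.bed
cleavemap logo --fasta demo.fasta --peaks peaks.bed --out-prefix demo
cleavemap run --config run.yaml --out-dir out/   # full pipeline + manifest
```

Each subcommand takes a flat YAML `--config` whose keys mirror the flags;
explicit flags win. All randomness flows from `--seed`.

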