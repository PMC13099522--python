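# dyadvr

Analysis of dyadic fighting-like interaction between two adult zebrafish
in a shared circular virtual-reality arena.

In the paradigm this package targets, two head-fixed fish swim through
avatars in one virtual arena (radius 100 VR units; 25-unit avatars;
100 ms frames; 30-min trials) and can approach, face and "bite" each
other, with a bite-contingent electric-shock schedule motivating the
fight. Given per-frame logs of both fish (position, heading, forward
speed, turning speed), `dyadvr` computes the behavioral statistics of
the paradigm:

* **Approach episodes** — spans of monotonically shrinking inter-fish
  distance attributed to the faster, target-facing fish; *bite events* —
  rising-edge mouth-to-mid-body collisions within ±75° of the
  perpendicular to the opponent's body axis; *attack-posture*, *near*
  (distance ≤ 50) and *center-occupancy* (inside the 70-unit inner
  circle) rates.
* **Attraction** — the fractional reduction of mean mutual distance
  relative to a position-shuffled null,
  `(mean(d_shuf) − d_real) / mean(d_shuf)` over 10 random permutations.
* **Eye-use laterality** — with the opponent classified per frame into
  the left monocular [−135°, −30°), binocular [−30°, +30°] or right
  monocular (30°, 135°] field: the percentages LEP / FBVP / REP (common
  non-blind denominator), the left-eye index
  `LEI = (N_left − N_right) / (N_left + N_right)`, distance-binned
  profiles, and high/low-proximity splits of approaches.
* **Transfer entropy** — discrete plug-in estimate of
  `T(P→Q) = H(Q_t|Q_{t−1}) − H(Q_t|Q_{t−1}, P_{t−1})` (bits) between the
  two fish's symbolized ethograms (4-symbol sign-change ethogram;
  5-level percentile-binned speed and turn), plus the net flow ΔTE.
* **Shock protocol simulation** — the 0.5 V / 300 ms-per-second mild
  cycle, 4 V / 100 ms bite transients and 2-min biter relief as a
  discrete-event schedule over a bite stream.
* **Group statistics** — two-sided Wilcoxon signed-rank (condition
  contrasts) and rank-sum (group contrasts) tests with the standardized
  mean difference `(μ1 − μ2)/σ` as effect size.
* **Synthetic dyads** — a seeded generator with controllable mutual
  attraction, lag-1 speed coupling and lateral eye-use bias, scripted
  single-approach trials with exact view-label ground truth, and an
  analytic transfer-entropy channel.

See `docs/methods.md` for definitions, conventions and design choices.

## Worked example

```python
import dyadvr as dv

config = dv.ArenaProtocolConfig()

# a synthetic 2-minute trial with mutual attraction and A->B speed coupling
trial = dv.generate_dyad(
    dv.SimParams(n_frames=1200, seed=7, attraction_gain=0.15, coupling_gain=0.8),
    config,
)

episodes = dv.detect_approaches(trial, config)
bites = dv.detect_bites(trial, config)
print(f"approaches: {len(episodes)}, bites: {len(bites)}")
print(f"near rate: {dv.near_rate(trial, config):.1f}%")
print(f"attraction: {dv.attraction(trial, seed=0):.3f}")
print(f"speed TE a->b minus b->a: {dv.te_bundle(trial)['speed'].delta_te:.4f} bits")
```

prints

```
approaches: 66, bites: 8
near rate: 98.5%
attraction: 0.755
speed TE a->b minus b->a: 1.1726 bits
```

66 approach episodes and 8 bite events were detected in 1200 frames; the
fish were within 50 units of each other 98.5% of the time; the observed
mean distance is 75.5% below the shuffled-null expectation (strong
attraction); and the large positive ΔTE of the percentile-binned speeds
correctly points from the leader A to the strongly coupled follower B.

The same pipeline runs from the shell:

```sh
dyadvr simulate --n-trials 4 --seed 1 --out runs/sims
dyadvr analyze runs/sims/trial_*.csv --out runs/analysis
dyadvr compare runs/analysis/trial_metrics.csv --metric near_rate --out runs/cmp
dyadvr make-fixtures --out runs/fixtures
```

Trial logs are long-form CSV (`frame,fish_id,x,y,heading,speed,turn`);
every command writes a YAML manifest with the config snapshot and seeds
that reproduce its outputs.

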