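# biocyberloop

A headless, fully testable implementation of an EEG-driven **biocybernetic
loop** for dynamic difficulty adjustment: band power derived from two EEG
channels covertly adapts the drop speed of a simulated Tetris game so that the
player is steered away from boredom and overload and toward an engaging level
of challenge.

## The loop

Two measures index the player's momentary state:

* **frontal midline theta** (Fz, 4–8 Hz) — rises with mental effort and
  cognitive control, falls when effort is withdrawn;
* **parietal upper alpha** (P4, 10.5–13 Hz) — suppressed by cortical
  activation, so *low* upper alpha means *high* task demand.

A resting baseline (relaxation period) yields per-user reference powers
`θ₀, α₀`. During play, each 5-s epoch's band powers `θ, α` are reduced to
ratios `rθ = θ/θ₀`, `rα = α/α₀` and classified against a trigger percentage
`T` (liberal 100 %, moderate 150 %, conservative 200 %), read
ratio-symmetrically on linear power:

```
up:    r ≥ 1 + T/100          down:  r ≤ 1 / (1 + T/100)

θ down ∧ α up    → boredom   → demand level +1
θ down ∧ α down  → overload  → demand level −1
otherwise        → engagement / zone → hold
```

Demand levels 1–10 map geometrically onto drop speeds 2.5–20 board
squares/s. Game death (blocks reach the top) resets the board at the slowest
speed. Epochs contaminated by >100 µV activity are excluded and never adapt
the game.

Because no recorded EEG ships with the package, a synthetic generator
produces Fz/P4 streams whose theta and upper-alpha RMS follow a scripted
state timeline (narrowband filtered noise on a 1/f background), giving every
downstream stage a ground truth to be tested against.

## Worked example

A fixed-demand game (180 s, slowest preset, coin incentive), played by the
built-in bot at full skill:

```console
$ biocyberloop play-fixed --preset low --duration 180 --seed 7
pieces=27 cleared_rows=10 performance=92.59% coins=64
```

27 tetrominoes (108 squares) could fill at most 10.8 rows; the bot cleared 10
of them (92.6 %), accruing 64 of the 70 achievable coins at the 10-s
accrual points.

A 5-minute closed-loop session against a synthetic stream scripted to satisfy
the boredom trigger in every epoch:

```console
$ biocyberloop run-loop --profile liberal --seed 5 --out session/
increases=60 decreases=0 resets=6 mean_difficulty=5.08 final_level=8
```

All 60 epochs classify as boredom, so the controller pushes demand up every
5 s; the resulting speed overwhelms the simulated player six times, each game
death restarting at level 1 — which is why the time-weighted mean difficulty
sits at 5.08 rather than 10. `session/` receives the per-epoch adaptation
log, the game event log and a config snapshot.

Classifier parameter recovery against scripted ground truth:

```console
$ biocyberloop recover --strengths 3 --profiles liberal,conservative --n 3 --seed 2
     profile  strength  accuracy  boredom_recall  overload_recall
     liberal       3.0    1.0000             1.0           1.0000
conservative       3.0    0.9889             1.0           0.9333
```

At deviation strength 3 the liberal (100 %) system recovers every scripted
epoch; the conservative (200 %) system misses a fraction of overload epochs,
as its trigger demands larger deviations than the script provides.

## Package layout

| module | contents |
| --- | --- |
| `biocyberloop.synth` | scripted two-channel EEG generator, artifact injection |
| `biocyberloop.spectral` | Kaiser FIR bandpass, windowed FFT spectra, band power, artifact exclusion, theta-window individualisation, epoch aggregation |
| `biocyberloop.states` | baseline calibration, deviation ratios, quadrant classifier, controller actions |
| `biocyberloop.tetris` | headless game engine (fixed-demand and adaptive modes), coin incentive, bot player |
| `biocyberloop.loop` | closed-loop session runner, manual-control benchmark |
| `biocyberloop.metrics` | session behaviour metrics, four-system comparison, recovery sweeps |
| `biocyberloop.sigio` | plain-text signal/sidecar/table formats |
| `biocyberloop.cli` | `biocyberloop` command with the subcommands used above |

See `docs/methods.md` for the modelling choices, parameter conventions and
known limitations.
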