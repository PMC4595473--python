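# ipr-gating

Modal gating of the IP3 receptor (IP3R) Ca²⁺ release channel under wild-type
versus familial-Alzheimer's-mutant presenilin-1 (PS1-WT vs PS1-M146L), as a
tested Python package: the twelve-state aggregated Markov model of
single-channel gating, its dwell-time theory and likelihood machinery, a
synthetic gating-record generator, and a stochastic reaction–diffusion
simulation of local Ca²⁺ release (puffs and blips) from a ten-channel
cluster.

It is written for computational biophysicists and Ca²⁺-signaling modelers
who want to reproduce, probe, or extend the quantitative claim that
FAD-causing presenilin mutations sensitize IP3R gating — shifting the
channel from its low-activity (L) gating mode into its high-activity,
bursting (H) mode — and to propagate that single-channel change up to local
Ca²⁺ release events.

## The model

Twelve states `XmnM` (conductance X ∈ {C, O}, m Ca²⁺ and n IP3 bound, mode
M ∈ {L, I, H}; three open states O14I, O24I, O24H).  Each state has an
occupancy parameter K so its equilibrium weight at ligand concentrations
(𝒞, ℐ) is Z_s = K_s·𝒞^m·ℐ^n, giving

    Po(𝒞, ℐ) = Z_O / Z,     π^M = Z^M / Z,
    τ_o = Z_O / J,  τ_c = Z_C / J,  τ^X = Z^X / J_X,

with J the equilibrium open→closed probability flux.  Transition rates are
flux parameters divided by occupancies (harmonically composed for
multi-step transitions), assembled into a 12×12 generator Q partitioned
into open/closed blocks.  Dwell-time densities follow from sub-generator
exponentials, f_X(t) = π_X·e^(Q_XX t)·Q_XY·1, and idealized records enter a
product-form likelihood π_C·e^(Q_CC t_c1)·Q_CO·e^(Q_OO t_o1)·…·1_O that is
maximized over flux parameters after a least-squares fit of the occupancy
parameters to measured (Po, π_L, π_I, π_H).

The PS1-M146L mutant differs from wild type in exactly four occupancy
parameters and two flux parameters; both printed parameter sets ship with
the package (`OccupancyParams.wild_type()` / `.m146l()`, same for
`FluxParams`).

## Worked example

```python
from ipr_gating import *

lig = LigandCondition(ca=1.0, ip3=0.1)  # 1 uM Ca2+, 100 nM IP3
for variant in ("WT", "M146L"):
    occ = OccupancyParams.for_variant(variant)
    flux = FluxParams.for_variant(variant)
    s = equilibrium_summary(occ, flux, lig)
    print(f"{variant:6s} Po={s.Po:.3f}  pi_L={s.pi_L:.3f} pi_I={s.pi_I:.3f} "
          f"pi_H={s.pi_H:.3f}  tau_o={s.tau_o_ms:.1f} ms tau_c={s.tau_c_ms:.1f} ms "
          f"tau_H={s.tau_H_ms:.0f} ms")

res = ligand_sweep(OccupancyParams.wild_type(), OccupancyParams.m146l())
print(f"max Po ratio (M146L/WT): {res.max_po_ratio:.0f}-fold")
print(f"mutant Po at 1 uM Ca matches WT@100nM already at "
      f"{res.po_crossing_ip3_uM*1e3:.1f} nM IP3")
```

prints

```
WT     Po=0.289  pi_L=0.518 pi_I=0.139 pi_H=0.343  tau_o=11.5 ms tau_c=28.3 ms tau_H=652 ms
M146L  Po=0.812  pi_L=0.059 pi_I=0.104 pi_H=0.836  tau_o=18.0 ms tau_c=4.2 ms tau_H=2378 ms
max Po ratio (M146L/WT): 128-fold
mutant Po at 1 uM Ca matches WT@100nM already at 7.1 nM IP3
```

Read: at the fitting condition (optimal 1 µM Ca²⁺, subsaturating 100 nM
IP3) the mutant channel spends 84% of its time in the bursting H mode
versus 34% for wild type, shortening the mean closed time from 28 ms to
4 ms and nearly tripling the open probability; across the ligand plane the
gain-of-function enhancement peaks above 100-fold, and ~7 nM IP3 suffices
to drive the mutant to the activity wild type needs 100 nM to reach.

Higher up the stack:

```python
# synthetic single-channel records and modal segmentation
traces = simulate_ensemble(occ, flux, lig, seed=0)
print(empirical_summary(traces))

# ten-channel cluster: 100 s of Ca2+ puffs and blips at 100 nM IP3
trace = run_cluster(occ, flux, LigandCondition(0.07, 0.1), duration_s=100, seed=1)
events = detect_events(trace)
```

A CLI mirrors the library (`ipr-gating curves | dwell | simulate-gating |
fit-occupancy | fit-flux | simulate-cluster | events | sweep`); every
subcommand takes a seed and writes CSV/JSON with a provenance header.

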