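# zipbind

Binding kinetics of a tethered Gaussian chain adsorbing onto a straight line
of surface receptors — for polymer physicists and biophysicists modelling
ordered self-assembly: an unfolded protein or designed multivalent chain
whose `M` evenly spaced ligands must find their matching receptors on a
surface.

## The model

An ideal chain of `N` segments of length `b` is grafted to a flat reflecting
wall; a ligand at its end seeks a hemispherical capture zone of radius `ε`
around a receptor a distance `a` away.  The mean first-passage time is
dominated by the entropic barrier `ΔG = 3k_BT a²/2Nb²` of stretching the
chain:

    τ_on(a, N) = N²b⁴/(9Dε²) · exp(3a²/2Nb²)

with `D` the monomer diffusion coefficient.  With `M` ligands spaced
`ΔN = N/M` monomers apart and receptors `Δa = a/M` apart, full adsorption is
an absorbing continuous-time Markov chain over the number of receptors left
to bind: single zipper steps at rate `k₁ = 1/τ_1a` plus loop-forming jumps
across `q ≥ 2` receptors at rates

    k_q = 1/τ_qa,    τ_qa = q² exp(3(q−1)MΔa²/2Nb²) · τ_1a .

Truncating at double steps gives the closed-form mean adsorption time and
its Taylor form `⟨τ(M)⟩ ≈ (M − (M−1)/2 · e^{−3MΔa²/2Nb²}) τ_1a`.  Early
binding events of a long chain are limited not by reaching but by the slow
centre-of-mass drift of the remaining free chain ("stem and flower"),
`τ_drift = 2N_f²b²/3D`; partitioning the `M` events at the crossover `m*`
gives the total adhesion time

    τ = Σ_{m≤m*} τ_drift(N_f(m)) + (M − m*) τ_1a ,

which is minimised by an optimal receptor number `M_opt` — more receptors
shorten each reach but weaken the entropic force that drags the chain along.

All lengths are in units of `b` and times in units of `b²/D` by default
(`b`, `D` are explicit parameters, so dimensional input works too).

## Worked example

Optimal receptor number for a 100-segment chain whose end must bind 40
segment-lengths away (`ε = b`):

```
$ zipbind optimal --N 100 --a 40
 M_discrete   M_root  M_asymptotic  search_lo  search_hi      tau_min
          6 6.261994      5.000089          1        200 19314.643522
```

The discrete scan of the drift/reach-partitioned adhesion time is fastest at
`M = 6` receptors (total time ≈ 1.93·10⁴ b²/D); the real root of the
stationarity condition `16Nε³M⁴ = 2√6 a²b·e^{9a²/4MNb²}` is 6.26, and the
leading-order asymptote is 5.0.  Compare a single end ligand, which needs
`τ_on ≈ 2.9·10¹³ b²/D` to cross the full barrier:

```
$ zipbind single --N 100 --a 40
  N    a  tau_closed_form
100 40.0     2.943236e+13
```

The drift/reach breakdown for densely spaced receptors shows every event
drift-limited (`m* = M`):

```
$ zipbind drift --N 100 --M 10 --delta-a 1.0
  total_time   drift_part  reach_part  m_star  m_star_com  m_star_drift
25666.666667 25666.666667         0.0      10    9.709073     10.559956
```

and the kinetic Monte-Carlo oracle reproduces the analytic chain solution
(here the accelerated zipper beats the pure-zipper time `Mτ_1a ≈ 826`):

```
$ zipbind simulate --N 100 --M 20 --delta-a 3 --q-max 2 --n-traj 20000 --seed 1
 mean_time      sem  n_traj  seed
799.425227 1.272858   20000     1
```

Scan tables (adsorption time vs loop cutoff, receptor number, or chain
length; adhesion time vs receptor number) are regenerated with
`zipbind scan {loop-cutoff,zipper-scan,zipper-density,adhesion-scan,adhesion-density}`
and written as commented CSV with `--out`.  Parameters can also come from a
YAML file via `--config`; flags override it.

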