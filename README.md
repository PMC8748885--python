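# normscan

Tools for studying cooperation through **indirect reciprocity with public
reputations**: mean-field reputation dynamics, cooperative-ESS tests, and
exhaustive scans of social-norm spaces with permutation-symmetry reduction.

## The problem

In the one-shot donation game a donor either pays a cost *c* to give a
benefit *b* > *c* to the recipient, or defects for free. Cooperation can
survive when players carry public reputations: a **social norm** is the pair
of an *assignment rule* `R(X, Y, A) → Z` (the reputation a donor with
reputation X earns after action A ∈ {C, D} toward a recipient with
reputation Y) and an *action rule* `P(X, Y) → A` (the prescribed action).
With two reputation labels (B, G) the celebrated *leading eight* are the
only norms that sustain stable cooperation. This package implements the
same machinery for **three labels** (B, N, G) — a space of
3¹⁸ × 2⁹ ≈ 2 × 10¹¹ norms, reduced to 64,573,605 × 512 = 33,061,685,760
independent ones by the reputation-relabelling symmetry.

Two kinds of error drive the dynamics: an implementation error μₑ (a donor
meaning to cooperate defects by mistake; never the reverse) and an
assignment error μₐ (the population mis-records a new reputation, each
wrong label with probability μₐ/2). The share hᴢ of players with
reputation Z follows

    dh_Z/dt = Σ_{X,Y} h_X h_Y K(X, Y → Z) − h_Z ,

whose stationary state h\* gives the cooperation level
p_c = Σ h_X h_Y [P(X,Y) = C]. A norm is a **cooperative ESS (CESS)** when
p_c ≥ 0.99 at μ = 10⁻³ and the resident payoff
π_res = p_c (1−μₑ)(b−c) strictly exceeds the payoff of a rare mutant using
any of the 2⁹ − 1 alternative action rules, for every b/c in
{1.1, 1.5, 2, …, 10} (the *core set*). Core norms are classified into
twelve subclasses: **C1/C2/C3** by the scaling of the stationary neutral
fraction h_N\* with μ (order μ, √μ, 1), **P1/P2** by whether punishment is
fully or partially justified, and **R1/R2** by one-step versus gradual
reputation recovery.

## Worked example

Twelve example norms (one per subclass) ship with the package:

```
$ normscan fixtures examples/
$ normscan check examples/c1p1r1.norm
norm         94785036-438  (BB:DG:B BN:DN:B BG:CG:N NB:DB:N NN:DN:B NG:CG:B GB:DG:N GN:DG:N GG:CG:B)
mu_e, mu_a   0.001, 0.001
h*           (0.0015, 0.0005, 0.9980)
p_c          0.9980
b/c = 1.1   CESS
...
b/c = 10    CESS
core set     yes
class        C1-P1-R1 (slope 1.001)
```

Reading the output: at error rate 10⁻³ almost everyone holds reputation G
(h_G\* = 0.998) and cooperates (p_c = 0.998); the norm resists every
behavioural mutant across the whole b/c range; the neutral fraction scales
as μ¹·⁰ (slope ≈ 1), so the norm is of type C1, with fully justified
punishment (P1) and instantaneous recovery (R1) — the ternary analogue of a
leading-eight norm.

Exhaustive sweeps run through `normscan scan`:

```
$ normscan scan --scope binary-full            # recovers exactly 8 CESSs
$ normscan scan --scope ternary-second-order --classify
scanned 996, pruned 421, core CESS 33          # 18 + 9 + 6 over three subclasses
```

and `normscan graph examples/c1p2r1.norm` exports the stationary
reputation-transition graph (DOT/JSON; dashed edges are error-driven).

The same functionality is available as a library:

```python
from normscan import ErrorModel, stationary, classify, load_fixture

norm = load_fixture("c3p2r2")
res = stationary(norm, ErrorModel.tied(1e-3))
print(res.h_star)          # [0.0061 0.3784 0.6155]
print(classify(norm).label)  # C3-P2-R2
```

This norm belongs to the family whose neutral fraction converges to the
inverse golden ratio squared, h_N\* → (3 − √5)/2 ≈ 0.38, as μ → 0.

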