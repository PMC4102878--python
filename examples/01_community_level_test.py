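"""Community-level co-occurrence test between two simulated ecosystems.

Simulates a replicated two-ecosystem study in which each ecosystem has its
own strong, replicate-consistent taxon correlation blocks, builds the
Spearman distance matrix (1 - rho) over taxon-replicate profiles, and asks
with a PERMANOVA whether co-occurrence structure differs by ecosystem.
"""

from cooccurnet import (
    permanova,
    preset_null,
    preset_signal,
    simulate_study,
    spearman_distance_matrix,
)

for name, preset in [("signal", preset_signal), ("null", preset_null)]:
    study = simulate_study(preset(seed=1))
    dm = spearman_distance_matrix(study)
    res = permanova(dm, n_permutations=9999, seed=1)
    print(f"{name:>6}: pseudo-F = {res.pseudo_F:6.3f}  "
          f"R^2 = {res.r_squared:.4f}  p = {res.p:.4f}")

print(
    "\nThe signal study (ecosystem-specific correlation blocks) rejects the\n"
    "null decisively (p << 0.02); the null study (all taxa independent) does\n"
    "not - within-ecosystem taxon pairs are no closer than cross-ecosystem\n"
    "ones, so ecosystem explains essentially none of the distance variance."
)
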