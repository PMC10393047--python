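"""Model how interaction strength responds to water temperature.

Simulates a ring community whose first half receives temperature-amplified
interactions and second half temperature-damped ones, runs the S-map stage
on the true edges, and fits community- and species-level gamma(log) smooths
of |IS| against temperature.
"""
from edmnet.benchmarks import (
    _ring_community,
    _sensitivity_panel,
    _truth_interactions,
)
from edmnet.sensitivity import (
    fit_strength_model,
    species_temperature_effects,
    strength_table,
)
from edmnet.smap import interaction_strengths

n = 8
params = _ring_community(n, gamma_pos=0.6, gamma_neg=-0.6, beta=0.1, seed=5)
panel, long_df, names = _sensitivity_panel(params, n_sites=2, T=100, seed=5)
iset = _truth_interactions(params, names)
is_frame, _ = interaction_strengths(panel, iset, seed=5, E_max=3)
obs = strength_table(is_frame, long_df)

fit = fit_strength_model(obs, predictor="temperature", direction="in", seed=5)
print(f"community in-strength vs temperature: p={fit.p_smooth:.3g}, "
      f"class={fit.sign_class}, n={fit.n_obs}")

eff = species_temperature_effects(obs, direction="in")
print(eff[["species", "n", "p_value", "sign_class", "highlight"]].to_string(index=False))
print("\nSpecies sp00-sp03 receive temperature-amplified interactions "
      "(expected 'increasing'), sp04-sp07 temperature-damped ('decreasing').")
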