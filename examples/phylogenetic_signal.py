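"""Pagel's λ, PGLS and ancestral states on a simulated phylogeny.

Evolves a continuous trait under Brownian motion on a 60-tip pure-birth
tree, estimates the phylogenetic signal (λ) with its likelihood-ratio
test, runs a PGLS regression against a correlated climate covariate,
and reconstructs ancestral states.
"""

from camtraits import ancestral_states, fit_lambda, pgls
from camtraits.simulate import (
    simulate_bm_traits,
    simulate_climate_covariates,
    simulate_tree,
)

tree = simulate_tree(60, seed=10)
labels, trait = simulate_bm_traits(tree, sigma2=1.0, lam=1.0, root=50.0, seed=11)

fit = fit_lambda(trait, tree)
print(f"Pagel's lambda: {fit.lam:.3f}  (true 1.0)")
print(f"logL = {fit.loglik:.2f}, logL(lambda=0) = {fit.loglik_lambda0:.2f}, "
      f"LRT p = {fit.pvalue:.2e}")

climate = simulate_climate_covariates(tree, trait, target_correlation=0.7, seed=12)
fit_pgls = pgls(trait, climate["BIO1"].to_numpy(), tree, structure="lambda",
                names=("BIO1",))
print("\nPGLS of the trait on the correlated covariate BIO1:")
print(fit_pgls.summary().to_string(float_format=lambda v: f"{v:.4g}"))
print(f"residual structure: lambda = {fit_pgls.lambda_used:.3f}")

anc = ancestral_states(trait, tree)
print(f"\nroot state estimate: {anc.root_state:.2f}  (true root 50.0)")
print(f"internal nodes reconstructed: {len(anc.states)}")

# Strong Brownian signal yields lambda near 1 with a tiny LRT p-value;
# the PGLS slope on BIO1 is significantly positive because the covariate
# was built with a 0.7 correlation to the trait.
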