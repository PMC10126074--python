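"""Calibrate Rasch and 2PL models on simulated respondents.

Simulates 500 respondents on 22 Rasch items, fits both models, compares
them with a likelihood-ratio test and BIC, and reports EAP abilities with
the empirical marginal reliability.
"""

import numpy as np

from voicetest import irt
from voicetest.simulate import RespondentModel, simulate_responses

rng = np.random.default_rng(1)
b_true = rng.uniform(-2, 2, 22)
responses = simulate_responses(RespondentModel(difficulty=b_true), 500, seed=2)

rasch = irt.fit_rasch(responses)
two_pl = irt.fit_2pl(responses, compute_se=False)
lr = irt.lr_test(rasch, two_pl)

b_hat = rasch.difficulty - rasch.difficulty.mean() + b_true.mean()
rmse = np.sqrt(np.mean((b_hat - b_true) ** 2))
print(f"Rasch: loglik {rasch.loglik:.1f}, latent SD {rasch.latent_sd:.3f}, "
      f"difficulty RMSE vs truth {rmse:.3f}")
print(f"LR test 2PL vs Rasch: chi2({lr.df}) = {lr.chi2:.2f}, p = {lr.p:.3f}")
print(f"BIC: Rasch {rasch.bic:.1f} vs 2PL {two_pl.bic:.1f} "
      f"-> {'Rasch' if rasch.bic < two_pl.bic else '2PL'} preferred")

abilities = irt.eap_abilities(rasch, responses)
reliability = irt.empirical_reliability(abilities)
print(f"EAP abilities: mean {abilities.theta.mean():.3f}, SD {abilities.theta.std():.3f}")
print(f"empirical marginal reliability: {reliability:.3f}")

theta, info, se = irt.test_information(rasch)
peak = theta[np.argmax(info)]
print(f"test information peaks at theta = {peak:.2f} (SE there: {se[np.argmax(info)]:.3f})")
# A non-significant LR test and smaller Rasch BIC mean the common-slope
# model suffices; reliability ~0.75+ is typical for 22 informative items.
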