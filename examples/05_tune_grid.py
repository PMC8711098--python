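"""Sweep hyperparameters over a grid of cross-validated RMSE cells.

The sweep shares one CV seed across cells so differences reflect the
hyperparameters, not the fold split.
"""

from mlaprbfn import Hyperparams, generate_multiview_fixture, tune_grid

fixture = generate_multiview_fixture(n=60, d=3, noise_sd=0.3, seed=0)
base = Hyperparams(p=20, tmax=5, seed=0)

surface = tune_grid(
    fixture,
    base,
    grid={"p": [10, 20, 30], "lambda1": [2.0**-5, 2.0**-3, 2.0**-1]},
    folds=5,
    seed=0,
)
print(surface[["p", "lambda1", "rmse", "is_best"]].to_string(index=False))
best = surface[surface.is_best].iloc[0]
print(f"\nbest cell: p={int(best.p)}, lambda1={best.lambda1}, "
      f"RMSE={best.rmse:.4f}")
print("\nEach row is one full 5-fold CV run; the arg-min row is flagged.")
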