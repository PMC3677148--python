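"""Fit the heteroscedastic Bayesian repeated-measures model to the bias table.

Standardizes the pooled (addition, subtraction) bias scores, runs the
Gibbs sampler (600,000 iterations, 100,000 burn-in by default), and
reports the 13-row posterior summary with 95% HDIs and sign probabilities.
"""

import sys
from pathlib import Path

import click
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from opmomentum import bayes  # noqa: E402


@click.command()
@click.option("--bias", "bias_path", type=click.Path(exists=True),
              default="results/descriptives/bias.csv")
@click.option("--iters", type=int, default=600_000)
@click.option("--burn", type=int, default=100_000)
@click.option("--seed", type=int, default=1)
@click.option("--hdi", "hdi_mass", type=float, default=0.95)
@click.option("--out", type=click.Path(), default="results/bayes")
def main(bias_path: str, iters: int, burn: int, seed: int, hdi_mass: float,
         out: str) -> None:
    outdir = Path(out)
    outdir.mkdir(parents=True, exist_ok=True)
    bias = pd.read_csv(bias_path)
    data = bayes.model_data_from_bias(bias)
    click.echo(f"standardized {sum(len(v) for v in data.scores.values())} "
               f"subjects (grand mean {data.grand_mean:.4f}, "
               f"grand SD {data.grand_sd:.4f})")
    draws = bayes.gibbs_sample(data, bayes.Priors(), iters, burn, seed=seed)
    diag = bayes.convergence_diagnostics(draws)
    diag.to_csv(outdir / "diagnostics.csv", index=False)
    summary = bayes.summarize_posterior(draws, hdi_mass)
    summary.to_csv(outdir / "summary.csv", index=False)
    (outdir / "summary.json").write_text(bayes.summary_to_json(summary))
    draws.to_frame(thin=max(1, (iters - burn) // 5000)).to_csv(
        outdir / "draws.csv", index=False)
    click.echo(summary.to_string(index=False,
                                 float_format=lambda v: f"{v:.3f}"))
    eff = summary.set_index("quantity")
    click.echo(
        f"P(adult effect > 0) = {eff.loc['effect_adult', 'p_positive']:.3f}; "
        f"P(child effect < 0) = {1 - eff.loc['effect_child', 'p_positive']:.3f}; "
        f"P(interaction > 0) = {eff.loc['interaction', 'p_positive']:.3f}")


if __name__ == "__main__":
    main()
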