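"""Furchgott's method on each agonist pair, as the classical benchmark.

Equieffective concentrations are read off the fitted Hill curves of the
naive and inactivated datasets (12 levels, 10-90% of the lower maximum)
and the double-reciprocal regression yields q and Kd per agonist, for
comparison with the SABRE strategy-3/4 estimates.

Reads results/normalized_study.csv; writes results/furchgott/.
"""

import pathlib

from sabrefit import RunConfig, read_ec_table, run_pipeline

RESULTS = pathlib.Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    datasets = read_ec_table(RESULTS / "normalized_study.csv")
    config = RunConfig(strategies=("furchgott",), normalize=False,
                       outdir=RESULTS / "furchgott")
    bundle = run_pipeline(config, datasets)
    for agonist, res in bundle["furchgott"].items():
        if "error" in res:
            print(f"{agonist}: estimation failed ({res['error']})")
            continue
        print(f"{agonist}: q={res['q']:.3f}  logKd={res['logKd']:.3f} "
              f"(Kd={res['Kd_M']:.2e} M)  line R2={res['r_squared']:.5f}")
    print(f"wrote {RESULTS / 'furchgott'}")


if __name__ == "__main__":
    main()
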