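"""Generate the reference synthetic world and its input tables.

Writes a GBD-layout extract (prevalence + incidence, 1990-2019, 5-year age
groups, 5% relative uncertainty intervals), a lifetime-prevalence table
(four 10-year groups per sex, CI half-width 0.03), and a thinned copy of
the exact ground-truth solution, under results/fixtures/.
"""

from pathlib import Path

from migraine_states.synthetic import (default_ground_truth,
                                       default_lifetime_coefs, solve_truth,
                                       truth_at, write_fixtures)

OUTDIR = Path(__file__).resolve().parents[1] / "results" / "fixtures"


def main() -> None:
    truth = default_ground_truth(noise=0.05, seed=0)
    paths = write_fixtures(OUTDIR, truth, ci_halfwidth=0.03)
    solution = solve_truth(truth)

    coefs = default_lifetime_coefs()
    print("ground-truth world: logit-linear lifetime prevalence with")
    print(f"  b0={coefs.b0:.4f} b1={coefs.b1:.5f} "
          f"b2={coefs.b2:.4f} b3={coefs.b3:.5f}")
    for sex in ("male", "female"):
        row = {c: float(truth_at(solution, c, 60.0, sex))
               for c in ("p0", "p_a", "p_i")}
        print(f"  {sex}: at age 60 never={row['p0']:.3f} "
              f"active={row['p_a']:.3f} inactive={row['p_i']:.3f}")
    for name, path in paths.items():
        print(f"wrote {name}: {path}")


if __name__ == "__main__":
    main()
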