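"""Inferential layer on a small simulated cohort.

Fits the trial-level mixed models (band power ~ CS x Time x Region with
a random region slope per participant; PLI ~ CS x Time with a random
intercept), Bonferroni-corrects the band tests, and runs the post-hoc
within-condition block trends.  Uses the pipeline driver end to end.
"""

import json
import warnings

from megdeep import RunConfig, run_pipeline

warnings.simplefilter("ignore")

config = RunConfig(seed=5, n_participants=3, n_sensors=80,
                   design={"trials_per_block": 12, "blocks_per_phase": 8},
                   inversion={"n_restarts": 8}, models=["C", "HA"])
summary = run_pipeline(config, "scratch/example_stats_run")

mc = summary["model_comparison"]
print(f"model comparison: winner {mc['winner']}, "
      f"dF(HA) = {mc['dF']['HA']:.1f} (decisive: {mc['decisive']['HA']})")

stats = summary["stats"]
print("\nband-power CS effect (Bonferroni-corrected p):")
for band, r in stats["power_lme"].items():
    cs = next(t for t in r["terms"] if t["term"] == "CS")
    print(f"  {band:10s} beta = {cs['estimate']:+.3f}  "
          f"p_corr = {r['CS_p_bonferroni']:.4f}")

pli_terms = {t["term"]: t for t in stats["pli_lme"]["terms"]}
print(f"\nPLI CS x Time interaction: F = {pli_terms['CS:Time']['F']:.2f}, "
      f"p = {pli_terms['CS:Time']['p']:.4f}")
for cond, r in stats["pli_posthoc_time"].items():
    print(f"  {cond} block slope {r['slope']:+.4f}  p = {r['p']:.4f}")
print("\nExpected pattern: a negative theta CS coefficient (CS+ < CS-),"
      "\nno gamma CS effect, and a positive CS+-only PLI slope.")
print(json.dumps({"artefacts": summary["artefacts"]}, indent=2))
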