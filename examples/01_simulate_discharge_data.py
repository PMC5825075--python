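"""Generate a synthetic episode table plus DRG reference and inspect it.

The generator emulates state administrative discharge data: person-linked
episodes with ICD-10 diagnosis lists, a DRG, whole-day LOS and demographics,
alongside a DRG reference table with average overnight LOS, cost weight and
sixteen treatment-expense subcategories.  Latent flags (dementia,
complications, Charlson conditions) are written as recoverable codes and
also recorded in a ground-truth sidecar.
"""

import tempfile

from excesscost import GeneratorConfig, generate_drg_reference, generate_episodes, write_fixture

cfg = GeneratorConfig(n_persons=2000, n_drgs=50, seed=7)
ref = generate_drg_reference(cfg)
episodes, truth = generate_episodes(cfg, ref)

outdir = tempfile.mkdtemp(prefix="excesscost_demo_")
paths = write_fixture(outdir, episodes, ref, truth, cfg)

print(f"{len(episodes)} episodes for {cfg.n_persons} persons, {cfg.n_drgs} DRGs")
print(episodes.head(5).to_string(index=False))
print()
dem = truth.groupby("person_id")["dementia"].first().mean()
print(f"person-level dementia prevalence: {dem:.3f} (target 0.119)")
print(f"episodes above their DRG average (assigned): "
      f"{truth['above_average_assigned'].mean():.3f} (target 0.37)")
print(f"fixture written to {outdir}")
# Each row is one overnight discharge; the sidecar holds the latent truth the
# rest of the pipeline is expected to recover from the codes alone.
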