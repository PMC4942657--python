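"""A full simulated study: calibrate -> RCF -> locate -> quantify.

Generates a six-level standard series and a 31-sample batch (2% area CV),
fits curves, estimates correction factors, locates peaks by relative
retention time, quantifies every sample by QAMS, and measures recovery of
the generating truth.
"""

import warnings

import numpy as np

from qams import (
    GeneratorConfig,
    default_registry,
    fit_calibration,
    generate_sample_batch,
    generate_standard_series,
    locate_run,
    qams_concentration,
    rcf_from_dilution_series,
    strip_labels,
)

cfg = GeneratorConfig(seed=17)
levels, std_runs, truth = generate_standard_series(cfg, replicates=2)

level_by_id = {lv.level_id: lv for lv in levels}
points = {}
for run in std_runs:
    for p in run.peaks:
        points.setdefault(p.compound_id, []).append(
            (level_by_id[run.source].concentrations[p.compound_id], p.area)
        )
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    curves = {cid: fit_calibration(pts, cid) for cid, pts in points.items()}
rcf_table = rcf_from_dilution_series(levels, std_runs, default_registry())

runs, preps, batch = generate_sample_batch(cfg, n_crude=21, n_processed=10)
errors = {}
for run in runs:
    located, _ = locate_run(strip_labels(run), cfg.anchor_rt)
    loc = {p.compound_id: p for p in located.peaks if p.compound_id}
    for cid, res in qams_concentration(rcf_table, curves["loganin"], loc).items():
        if res.detected:
            true_c = batch.concentrations[run.run_id][cid]
            errors.setdefault(cid, []).append(abs(res.value / true_c - 1))

print(f"{len(runs)} samples quantified by QAMS; recovery of generator truth:")
for cid, errs in errors.items():
    print(f"  {cid:24s} mean |rel err| {100 * np.mean(errs):4.2f}%  (n={len(errs)})")
# Mean errors track the 2% injected area noise; crude samples contribute no
# 5-HMF / O-ethylmorroniside values because those peaks are absent.
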