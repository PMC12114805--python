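"""Random-forest phosphorus estimation from per-order optimal indices.

Features are the DSI values at the best band pair of each order in
{0, 1, 1.6, 2}; the model trains on a random 60 % calibration split and is
judged on the held-out 40 %.
"""

import specphos as sp

s = sp.generate_planted(sp.SynthConfig(mode="planted", seed=1))
orders = (0.0, 1.0, 1.6, 2.0)
frs = sp.fod_sweep(s, sp.FODConfig(orders=orders))
scans = [sp.scan_pairs(fr.matrix, s.lpc, "DSI", fr.wavelengths,
                       source_order=fr.order) for fr in frs]
feats = sp.build_features(frs, scans, "DSI")
split = sp.make_split(s.n_samples, 0.6, seed=1, sample_ids=s.sample_ids)
rep = sp.fit_and_evaluate(feats, s.lpc, split, sample_ids=s.sample_ids,
                          index_kind="DSI")

print(f"split: {len(split.calibration_ids)} calibration / "
      f"{len(split.validation_ids)} validation")
print(f"calibration: R^2 = {rep.r2_cal:.2f}  RMSE = {rep.rmse_cal:.4f} mg/g")
print(f"validation:  R^2 = {rep.r2_val:.2f}  RMSE = {rep.rmse_val:.4f} mg/g")
print("Validation R^2 well above 0.7 shows the planted DSI signal carries "
      "through derivative transforms, pair search and the forest.")
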