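"""Evaluate simulated predictors with the full ligand-aware metric panel.

Generates a benchmark with one structure-trained-style track, one
disorder-trained-style track and one random track, then prints AUC,
AULCratio, calibrated operating points and the cross-/over-prediction
statistics for each, overall and per annotation source.
"""

from dbrmeta import (
    DEFAULT_TRACKS,
    SimConfig,
    Source,
    TrackSimConfig,
    compute_report,
    generate_dataset,
    simulate_tracks,
)

ds = generate_dataset(SimConfig(n_dna_proteins=30, n_other_proteins=120,
                                length_median=250, seed=1))
tracks = list(DEFAULT_TRACKS) + [TrackSimConfig("random", d_struct=0, d_dis=0)]
simulate_tracks(ds, tracks, seed=2)

subsets = {
    "all": None,
    "structure": ds.protein_ids(source=Source.STRUCTURE),
    "disorder": ds.protein_ids(source=Source.DISORDER),
}
for name, ids in subsets.items():
    print(f"\n=== {name} proteins ===")
    labels = ds.pooled_labels(ids)
    header = f"{'method':10s} {'AUC':>6s} {'AULCr':>6s} {'sens@0.1':>8s} {'CPRr':>6s} {'AUCPC':>6s} {'AUOPC':>6s}"
    print(header)
    for tc in tracks:
        rep = compute_report(labels, ds.pooled_scores(tc.predictor_id, ids))
        print(f"{tc.predictor_id:10s} {rep.auc:6.3f} {rep.aulc_ratio:6.2f} "
              f"{rep.sensitivity_at_fpr[0.1]:8.3f} {rep.cpr_ratio:6.2f} "
              f"{rep.aucpc:6.3f} {rep.auopc:6.3f}")

print(
    "\nReading the table: AULCratio is the low-FPR ROC area relative to a"
    "\nrandom predictor (1 = random); CPRratio > 1 means fewer other-ligand"
    "\nresidues are called DNA-binding than a random predictor would call at"
    "\nthe same FPR; AUCPC/AUOPC near 0.5 flag ligand-agnostic prediction."
    "\nNote how each structure-trained-style track collapses toward random"
    "\non disorder-annotated proteins and vice versa."
)
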