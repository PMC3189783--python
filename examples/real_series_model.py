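"""Fit the ligand-based CoMSIA model on the 60-compound APD series.

Builds the packaged 3-arylpyrimidin-2,4-dione dataset (uracil scaffold,
variable N1/C6/aryl substituents, pKi from a GABA-receptor binding assay),
embeds template-based conformers, aligns everything on the most potent
compound (58), computes the five similarity-index fields on a 2 Angstrom
lattice and fits a PLS model with leave-one-out cross-validation.
"""

from gridqsar import pipeline
from gridqsar.config import RunConfig

cfg = RunConfig()
records, aligned, reference = pipeline.build_aligned_series(cfg)
result = pipeline.run_real_model(records, aligned, cfg, family="comsia")

s = result.stats
print("Ligand-based CoMSIA model (45 training / 15 test compounds)")
print(f"  q2 (LOO)      = {s.q2:.3f}   cross-validated; > 0.5 indicates predictive power")
print(f"  SEP           = {s.sep:.3f}   standard error of prediction at Nc={s.n_components}")
print(f"  r2_ncv        = {s.r2ncv:.3f}   conventional fitted correlation")
print(f"  SEE           = {s.see:.3f}   standard error of estimate (log units)")
print(f"  F             = {s.f_stat:.1f}")
print(f"  r2_pred       = {s.r2pred:.3f}   external test set, outliers 14/21 excluded")
print("  field contributions (fraction of |coef|*sd):")
for kind, frac in sorted(s.field_fractions.items()):
    print(f"    {kind:22s} {frac:.3f}")

test_preds = result.predictions[result.predictions.test]
print("\nTest-set predictions (pKi):")
for _, row in test_preds.iterrows():
    mark = " (outlier, excluded from r2_pred)" if row.outlier else ""
    print(
        f"  compound {int(row.id):2d}: actual {row.actual:.1f}  "
        f"predicted {row.predicted:.2f}  residual {row.residual:+.2f}{mark}"
    )
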