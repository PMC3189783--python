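"""End-to-end model building: dataset -> alignment -> fields -> PLS -> contours.

`run_real_model` reproduces the ligand-based modelling protocol on the
packaged 60-compound series: build and embed the structures, superpose on
the most potent compound (58), lay a 2 Angstrom lattice with a 4 Angstrom
margin over the aligned union, compute either probe-interaction (CoMFA) or
similarity-index (CoMSIA) descriptor blocks, filter and scale, pick the
component count by leave-one-out cross-validation, and score the external
test set (the two documented outliers excluded from predictive r2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import alignment, contours, dataset, fields, pls, synthetic
from .config import RunConfig
from .molecule import Molecule3D

__all__ = ["ModelResult", "build_aligned_series", "run_real_model", "run_synthetic_model"]

FAMILIES = {
    "comfa": list(fields.COMFA_FIELD_KINDS),
    "comsia": list(fields.COMSIA_FIELD_KINDS),
}


@dataclass
class ModelResult:
    """Everything a downstream consumer needs from one fitted model."""

    family: str
    stats: pls.ModelStats
    loo: pls.LOOResult
    model: pls.PLSModel
    blocks: Dict[str, fields.FieldBlock]
    grid: fields.GridSpec
    predictions: pd.DataFrame
    contour_maps: Dict[str, contours.ContourMap] = field(default_factory=dict)


def build_aligned_series(config: RunConfig = RunConfig(), n_conformers: int | None = None):
    """Load the record table, build template-based conformer ensembles and
    align every conformer onto the reference compound's scaffold.

    Returns ``(records, ensembles, reference)`` where ``ensembles`` maps
    compound id to its aligned conformers and ``reference`` is the aligned
    template molecule.
    """
    records = dataset.load_table(config.input_path)
    kwargs = {} if n_conformers is None else {"n_conformers": n_conformers}
    ensembles = dataset.build_series_ensembles(
        records, seed=config.seed, reference_id=config.reference_id, **kwargs
    )
    reference = ensembles[config.reference_id][0]
    aligned = {
        cid: [alignment.align_to_reference(m, reference) for m in group]
        for cid, group in ensembles.items()
    }
    return records, aligned, aligned[config.reference_id][0]


def primary_conformers(ensembles) -> List[Molecule3D]:
    """First (representative) conformer of each compound, ordered by id."""
    if hasattr(ensembles, "items"):
        return [group[0] for _, group in sorted(ensembles.items())]
    return sorted(ensembles, key=lambda m: m.compound_id)


def _probe(config: RunConfig) -> fields.ProbeSpec:
    return fields.ProbeSpec(
        charge=config.probe_charge,
        radius=config.probe_radius,
        epsilon=config.probe_epsilon,
        alpha=config.alpha,
        truncation=config.truncation,
    )


def run_real_model(
    records: Sequence[dataset.CompoundRecord],
    aligned,
    config: RunConfig = RunConfig(),
    family: str = "comsia",
    with_contours: bool = True,
) -> ModelResult:
    """Fit one model family on the aligned real series and score it.

    ``aligned`` is either a flat list of aligned molecules or a mapping
    from compound id to its aligned conformers; in the latter case each
    compound's descriptor row is the ensemble mean of its conformer fields.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown model family {family!r}")
    probe = _probe(config)
    if hasattr(aligned, "items"):
        all_conformers = [m for group in aligned.values() for m in group]
    else:
        all_conformers = list(aligned)
    grid = fields.make_grid(
        all_conformers, spacing=config.grid_spacing, margin=config.grid_margin
    )
    if family == "comfa":
        blocks = fields.assemble_comfa_blocks(
            aligned, grid, probe, electrostatic_exclusion=config.electrostatic_exclusion
        )
        min_sd = config.min_sd_comfa
    else:
        blocks = fields.assemble_comsia_blocks(aligned, grid, probe)
        min_sd = config.min_sd_comsia

    recs = {r.id: r for r in records}
    train_ids = sorted(r.id for r in records if not r.is_test)
    test_ids = sorted(r.id for r in records if r.is_test)
    y_train = np.array([recs[i].pki for i in train_ids])
    y_test = np.array([recs[i].pki for i in test_ids])

    filtered = [
        pls.filter_columns(blocks[k].subset(train_ids), min_sd) for k in FAMILIES[family]
    ]
    desc = pls.combine_blocks(filtered)
    X_train = desc.X
    X_test = np.hstack(
        [
            blocks[fb.field_kind].subset(test_ids).matrix[:, fb.column_indices]
            for fb in filtered
        ]
    )

    loo = pls.loo_cv(
        X_train,
        y_train,
        max_components=config.max_components,
        column_scales=desc.column_scales,
        selection=config.component_selection,
    )
    model = pls.fit(
        X_train,
        y_train,
        loo.n_components,
        column_scales=desc.column_scales,
        column_field_kinds=desc.column_field_kinds,
        column_grid_indices=desc.column_grid_indices,
    )
    exclude = np.array([recs[i].is_outlier for i in test_ids])
    stats = pls.evaluate(
        model, X_train, y_train, X_test, y_test, loo=loo, exclude_test=exclude
    )

    pred_train = model.predict(X_train)
    pred_test = model.predict(X_test)
    rows = []
    for ids, preds, is_test in ((train_ids, pred_train, False), (test_ids, pred_test, True)):
        for cid, p in zip(ids, preds):
            rows.append(
                {
                    "id": cid,
                    "actual": recs[cid].pki,
                    "predicted": float(p),
                    "residual": recs[cid].pki - float(p),
                    "test": is_test,
                    "outlier": recs[cid].is_outlier,
                }
            )
    predictions = pd.DataFrame(rows).sort_values("id").reset_index(drop=True)

    cmap_dict: Dict[str, contours.ContourMap] = {}
    if with_contours:
        for kind in FAMILIES[family]:
            cmap = contours.stdev_coeff_map(model, blocks[kind].subset(train_ids))
            contours.contour_levels(cmap, config.favored_pct, config.disfavored_pct)
            cmap_dict[kind] = cmap

    return ModelResult(
        family=family,
        stats=stats,
        loo=loo,
        model=model,
        blocks=blocks,
        grid=grid,
        predictions=predictions,
        contour_maps=cmap_dict,
    )


def run_synthetic_model(
    spec: synthetic.SyntheticSpec,
    max_components: int = 5,
    min_sd: float = 0.05,
    field_kind: str = "comsia_S",
    selection: str = "parsimony",
):
    """Planted-signal validation: generate, run the pipeline, report recovery.

    Returns ``(truth, loo, model, cmap, report)``.  The leave-one-out q2 and
    the fitted model come from the training portion of the generated split.
    """
    mols, activities, truth = synthetic.generate(spec)
    aligned, _ = alignment.align_series(mols, reference_id=1)
    block = fields.assemble_block(aligned, truth.grid, fields.ProbeSpec(), field_kind=field_kind)

    all_ids = [m.compound_id for m in mols]
    test = set(truth.test_ids)
    train_ids = [i for i in all_ids if i not in test]
    y = {cid: a for cid, a in zip(sorted(all_ids), activities)}
    y_train = np.array([y[i] for i in train_ids])

    fb = pls.filter_columns(block.subset(train_ids), min_sd)
    desc = pls.combine_blocks([fb])
    loo = pls.loo_cv(
        desc.X,
        y_train,
        max_components=max_components,
        column_scales=desc.column_scales,
        selection=selection,
    )
    model = pls.fit(
        desc.X,
        y_train,
        loo.n_components,
        column_scales=desc.column_scales,
        column_field_kinds=desc.column_field_kinds,
        column_grid_indices=desc.column_grid_indices,
    )
    cmap = contours.stdev_coeff_map(model, block.subset(train_ids))
    contours.contour_levels(cmap)
    report = synthetic.recovery_report(truth, model, cmap, loo=loo)
    return truth, loo, model, cmap, report
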