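"""Save/load phantom cohorts as NIfTI + TSV + JSON directories.

Layout written by :func:`save_cohort` (and the ``simulate`` CLI)::

    <dir>/manifest.json                 generator spec + seed
    <dir>/atlas.nii.gz                  integer label volume
    <dir>/atlas_regions.tsv             label, region, hemisphere
    <dir>/brain_mask.nii.gz, ventricle_mask.nii.gz, exclusion_mask.nii.gz
    <dir>/scores.tsv                    subject_id, covariates, scores
    <dir>/sub-XXXX/<channel>.nii.gz     image channels
    <dir>/sub-XXXX/lesion_mask.nii.gz   synthetic ground truth
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .phantom import Cohort, spec_from_dict, spec_to_dict
from .volumes import (
    AtlasLabelMap,
    SubjectRecord,
    Volume,
    read_score_table,
    read_volume,
    write_score_table,
    write_volume,
)

__all__ = ["save_cohort", "load_cohort"]


def save_cohort(cohort: Cohort, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "manifest.json").write_text(
        json.dumps(spec_to_dict(cohort.spec), indent=1)
    )
    write_volume(cohort.atlas.labels, out / "atlas.nii.gz")
    pd.DataFrame([
        {"label": lab, "region": name,
         "hemisphere": cohort.atlas.region_hemisphere.get(lab, "none")}
        for lab, name in sorted(cohort.atlas.region_names.items())
    ]).to_csv(out / "atlas_regions.tsv", sep="\t", index=False)
    write_volume(cohort.brain_mask, out / "brain_mask.nii.gz")
    write_volume(cohort.ventricle_mask, out / "ventricle_mask.nii.gz")
    write_volume(cohort.exclusion_mask, out / "exclusion_mask.nii.gz")
    write_score_table(
        [(s.subject_id, s.scores, s.covariates) for s in cohort.subjects],
        out / "scores.tsv",
    )
    for s in cohort.subjects:
        sdir = out / s.subject_id
        sdir.mkdir(exist_ok=True)
        for name, vol in s.channels.items():
            write_volume(vol, sdir / f"{name}.nii.gz")
        if s.true_lesion_mask is not None:
            write_volume(s.true_lesion_mask, sdir / "lesion_mask.nii.gz")


def load_cohort(in_dir: str | Path) -> Cohort:
    src = Path(in_dir)
    spec = spec_from_dict(json.loads((src / "manifest.json").read_text()))
    names_df = pd.read_csv(src / "atlas_regions.tsv", sep="\t")
    atlas = AtlasLabelMap(
        labels=read_volume(src / "atlas.nii.gz", space_tag="phantom"),
        region_names={int(r.label): str(r.region)
                      for r in names_df.itertuples()},
        region_hemisphere={int(r.label): str(r.hemisphere)
                           for r in names_df.itertuples()},
    )
    records = read_score_table(src / "scores.tsv")
    subjects = []
    for sid, scores, covs in records:
        sdir = src / sid
        channels = {
            p.name.replace(".nii.gz", ""): read_volume(p, "phantom")
            for p in sorted(sdir.glob("*.nii.gz"))
            if p.name != "lesion_mask.nii.gz"
        }
        mask_path = sdir / "lesion_mask.nii.gz"
        mask = read_volume(mask_path, "phantom") if mask_path.exists() else None
        if mask is not None:
            mask = mask.with_data(mask.data.astype(np.uint8))
        subjects.append(SubjectRecord(
            subject_id=sid, channels=channels, scores=scores,
            covariates=covs, true_lesion_mask=mask,
        ))
    return Cohort(
        subjects=subjects,
        atlas=atlas,
        brain_mask=_as_mask(read_volume(src / "brain_mask.nii.gz", "phantom")),
        ventricle_mask=_as_mask(
            read_volume(src / "ventricle_mask.nii.gz", "phantom")),
        exclusion_mask=_as_mask(
            read_volume(src / "exclusion_mask.nii.gz", "phantom")),
        spec=spec,
    )


def _as_mask(v: Volume) -> Volume:
    return v.with_data(v.data.astype(np.uint8))
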