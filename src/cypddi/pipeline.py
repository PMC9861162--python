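"""End-to-end orchestration: config, staged execution, reports, manifest.

A ``RunConfig`` (YAML- or dict-loadable) names the stages to run and their
parameters; ``run_pipeline`` executes them in dependency order, writes CSV
outputs, a Markdown report and a JSON manifest (inputs, seeds, checksums).
Outputs carry no timestamps, so identical configs produce byte-identical
files.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from . import __version__, inhibition, nca, scaling, synthetic
from .ddi import dynamic_aucr, make_result, static_aucr
from .params import (
    CMAX_TOTAL_UM,
    CL_DOG_IN_VIVO_ML_MIN,
    DAPACONAZOLE_DOG,
    DAPACONAZOLE_HUMAN,
    DOG_CL_PREDICTED_ML_MIN,
    DOG_PHYSIOLOGY,
    DOG_QUALIFICATION_REFERENCE,
    DYNAMIC_SUBSTRATE_BY_ROW,
    FM_BY_ROW,
    FU_PLASMA_STATIC,
    HUMAN_PHYSIOLOGY,
    IC50_PANEL_UM,
    KIN_PER_H,
    KOUT_PER_H,
    VICTIM_SUBSTRATES,
    VSAC_L_KG,
    VSS_L_KG,
)
from .pbpk import DoseRegimen, PBPKModelSpec, simulate

__all__ = ["RunConfig", "run_pipeline", "ALL_STAGES"]

ALL_STAGES = ("ic50", "pbpk_dog", "scaling", "static_ddi", "dynamic_ddi", "report")


class RunConfig(BaseModel):
    """Validated pipeline configuration."""

    outdir: Path
    stages: tuple[str, ...] = ALL_STAGES
    seed: int = 0
    ic50_source: str = Field("reference", pattern="^(reference|synthetic)$")
    noise_cv: float = Field(0.1, ge=0.0)
    fu_inc: float = Field(0.94, gt=0.0, le=1.0)
    fu_plasma_static: float = Field(FU_PLASMA_STATIC, gt=0.0, le=1.0)
    cmax_total_um: float = Field(CMAX_TOTAL_UM, gt=0.0)
    use_rb_in_imax: bool = False
    perpetrator_dose_mg: float = Field(500.0, gt=0.0)
    perpetrator_interval_h: float = Field(8.0, gt=0.0)
    perpetrator_n_doses: int = Field(8, ge=1)
    victim_dose_time_h: float = Field(48.0, ge=0.0)
    dog_doses_mg_per_kg: tuple[float, ...] = (1.0, 2.0, 20.0)

    @field_validator("stages")
    @classmethod
    def _known_stages(cls, v: tuple[str, ...]) -> tuple[str, ...]:
        unknown = set(v) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        return v

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()))


def _md_table(df: pd.DataFrame) -> str:
    """Pipe-delimited Markdown table without external helpers."""
    cols = list(df.columns)
    rows = [[str(v) for v in rec] for rec in df.itertuples(index=False)]
    header = "| " + " | ".join(cols) + " |"
    rule = "| " + " | ".join("---" for _ in cols) + " |"
    body = ["| " + " | ".join(r) + " |" for r in rows]
    return "\n".join([header, rule, *body])


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def _stage_ic50(config: RunConfig, outdir: Path) -> pd.DataFrame:
    """IC50/Ki summary, from the measured panel or re-fitted synthetic plates."""
    fits: dict[tuple[str, str], inhibition.IC50Fit] = {}
    for i, ((cyp, substrate), ic50) in enumerate(sorted(IC50_PANEL_UM.items())):
        if config.ic50_source == "synthetic":
            plate = synthetic.gen_incubation_plate(
                ic50_true=ic50,
                noise_cv=config.noise_cv,
                seed=config.seed + i,
                isoform=cyp,
            )
            fits[(cyp, substrate)] = inhibition.fit_ic50_from_plate(
                plate.data).require_converged()
        else:
            # measured IC50: carried through as an exact, zero-SE fit
            fits[(cyp, substrate)] = inhibition.IC50Fit(
                ic50=ic50, hill_slope=1.0, standard_error=0.0,
                ci95=(ic50, ic50), converged=True, residuals=np.array([]),
            )
    summary = inhibition.summarize_panel(fits, fu_inc=config.fu_inc)
    _write_csv(summary, outdir / "ic50_summary.csv")
    return summary


def _dog_spec(dose_mg_per_kg: float) -> PBPKModelSpec:
    cl_ml_min = DOG_CL_PREDICTED_ML_MIN[dose_mg_per_kg]
    return PBPKModelSpec(
        vss=VSS_L_KG, vsac=VSAC_L_KG, kin=KIN_PER_H, kout=KOUT_PER_H,
        compound=DAPACONAZOLE_DOG, physiology=DOG_PHYSIOLOGY,
        cl_iv=cl_ml_min * 0.06,
    )


def _stage_pbpk_dog(config: RunConfig, outdir: Path) -> pd.DataFrame:
    """Simulate the dog IV doses, run NCA, and tabulate qualification ratios."""
    frames = []
    qual_rows = []
    for dose in config.dog_doses_mg_per_kg:
        spec = _dog_spec(dose)
        dose_mg = dose * DOG_PHYSIOLOGY.body_weight
        times = np.unique(np.concatenate([
            np.linspace(0.0, 12.0, 241), np.linspace(12.0, 120.0, 217),
        ]))
        prof = simulate(spec, DoseRegimen(amount=dose_mg), times)
        df = pd.DataFrame({
            "dose_mg_per_kg": dose,
            "time_h": prof.times,
            "conc_ng_ml": prof.plasma_conc,
            "conc_uM": prof.plasma_conc_um,
            "A_sys_mg": prof.a_sys,
            "A_sac_mg": prof.a_sac,
            "eliminated_mg": prof.eliminated,
        })
        frames.append(df)
        res = nca.run_nca(prof.times, prof.plasma_conc, dose_mg)
        observed = {
            "auc_0_t": DOG_QUALIFICATION_REFERENCE[dose]["auc_0_t"][1],
            "cmax": DOG_QUALIFICATION_REFERENCE[dose]["cmax"][1],
            "cl": DOG_QUALIFICATION_REFERENCE[dose]["cl"][1],
        }
        predicted = {"auc_0_t": res.auc_inf, "cmax": res.cmax, "cl": res.cl}
        for row in nca.qualification_table(predicted, observed):
            qual_rows.append({
                "dose_mg_per_kg": dose, "parameter": row.parameter,
                "predicted": row.predicted, "observed": row.observed,
                "ratio": row.ratio, "within_2fold": row.within_2fold,
            })
    _write_csv(pd.concat(frames, ignore_index=True), outdir / "dog_profiles.csv")
    qual = pd.DataFrame(qual_rows)
    _write_csv(qual, outdir / "dog_qualification.csv")
    return qual


def _stage_scaling(outdir: Path) -> dict[str, float]:
    params = scaling.AllometryParams(cl_dog=CL_DOG_IN_VIVO_ML_MIN, vss_dog=VSS_L_KG)
    human = {
        "cl_human_L_h": scaling.allometric_cl(params),
        "vss_human_L_kg": scaling.allometric_vss(params.vss_dog),
    }
    (outdir / "human_scaled_params.json").write_text(json.dumps(human, indent=2))
    return human


def _human_spec(human_scaled: dict[str, float]) -> PBPKModelSpec:
    return PBPKModelSpec(
        vss=human_scaled["vss_human_L_kg"], vsac=VSAC_L_KG,
        kin=KIN_PER_H, kout=KOUT_PER_H,
        compound=DAPACONAZOLE_HUMAN, physiology=HUMAN_PHYSIOLOGY,
        cl_iv=human_scaled["cl_human_L_h"],
    )


def _stage_static_ddi(config: RunConfig, ic50_summary: pd.DataFrame,
                      outdir: Path) -> pd.DataFrame:
    rows = []
    for (cyp, substrate), fm in FM_BY_ROW.items():
        match = ic50_summary[(ic50_summary["cyp"] == cyp)
                             & (ic50_summary["substrate"] == substrate)]
        ic50 = float(match["ic50_uM"].iloc[0])
        profile = inhibition.InhibitorProfile.from_ic50(
            ic50,
            fu_inc=config.fu_inc,
            fu_plasma=config.fu_plasma_static,
            cmax_total=config.cmax_total_um,
            rb=DAPACONAZOLE_HUMAN.blood_plasma_ratio,
            use_rb_in_imax=config.use_rb_in_imax,
        )
        from .ddi import compute_r1, r1_flag

        r1 = compute_r1(profile.imax_u, profile.ki_u)
        rows.append({
            "cyp": cyp, "substrate": substrate,
            "I_uM": config.cmax_total_um, "Imax_u_uM": profile.imax_u,
            "Ki_uM": profile.ki, "Ki_u_uM": profile.ki_u,
            "fm": fm, "R1": r1, "R1_flag": r1_flag(r1),
            "AUCR_static": static_aucr(fm, profile.imax_u, profile.ki_u),
        })
    df = pd.DataFrame(rows)
    _write_csv(df, outdir / "static_ddi.csv")
    return df


def _stage_dynamic_ddi(config: RunConfig, static_df: pd.DataFrame,
                       human_scaled: dict[str, float], outdir: Path) -> pd.DataFrame:
    spec = _human_spec(human_scaled)
    regimen = DoseRegimen(
        amount=config.perpetrator_dose_mg,
        n_doses=config.perpetrator_n_doses,
        interval=config.perpetrator_interval_h,
    )
    rows = []
    for _, row in static_df.iterrows():
        victim_name = DYNAMIC_SUBSTRATE_BY_ROW[(row["cyp"], row["substrate"])]
        victim = VICTIM_SUBSTRATES[victim_name]
        aucr = dynamic_aucr(
            spec, regimen, victim, ki_u=row["Ki_u_uM"],
            victim_dose_time=config.victim_dose_time_h,
            fu_plasma=config.fu_plasma_static,
        )
        rows.append({
            "cyp": row["cyp"], "substrate": row["substrate"],
            "dynamic_substrate": victim_name, "AUCR_dynamic": aucr,
        })
    df = pd.DataFrame(rows)
    _write_csv(df, outdir / "dynamic_ddi.csv")
    return df


def _stage_report(static_df: pd.DataFrame, dynamic_df: pd.DataFrame | None,
                  qual: pd.DataFrame | None, outdir: Path) -> pd.DataFrame:
    merged = static_df.copy()
    if dynamic_df is not None:
        merged = merged.merge(dynamic_df[["cyp", "substrate", "AUCR_dynamic"]],
                              on=["cyp", "substrate"], how="left")
    else:
        merged["AUCR_dynamic"] = 1.0
    results = [
        make_result(r["cyp"], r["substrate"], r["R1"], r["AUCR_static"],
                    r["AUCR_dynamic"])
        for _, r in merged.iterrows()
    ]
    merged["fda_class"] = [r.fda_class for r in results]
    merged["clinical_study_recommended"] = [
        r.clinical_study_recommended for r in results
    ]
    table = merged[[
        "cyp", "substrate", "I_uM", "Ki_uM", "R1", "fm",
        "AUCR_static", "AUCR_dynamic", "fda_class",
    ]]
    _write_csv(table, outdir / "ddi_table.csv")

    lines = ["# DDI prediction report", "", "## Inhibitor classification", ""]
    lines.append(_md_table(table.round(3)))
    if qual is not None:
        lines += ["", "## Dog model qualification (observed/predicted)", "",
                  _md_table(qual.round(3))]
    (outdir / "report.md").write_text("\n".join(lines) + "\n")
    return table


def run_pipeline(config: RunConfig) -> dict[str, object]:
    """Execute the configured stages in dependency order.

    Returns the in-memory outputs keyed by stage; files land in
    ``config.outdir``. Stages not requested but required by requested ones
    (e.g. ``ic50`` for ``static_ddi``) run implicitly.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    requested = set(config.stages)
    outputs: dict[str, object] = {}

    need_ic50 = requested & {"ic50", "static_ddi", "dynamic_ddi", "report"}
    if need_ic50:
        outputs["ic50"] = _stage_ic50(config, outdir)
    if requested & {"pbpk_dog", "report"}:
        outputs["pbpk_dog"] = _stage_pbpk_dog(config, outdir)
    if requested & {"scaling", "dynamic_ddi", "report"}:
        outputs["scaling"] = _stage_scaling(outdir)
    if requested & {"static_ddi", "dynamic_ddi", "report"}:
        outputs["static_ddi"] = _stage_static_ddi(config, outputs["ic50"], outdir)
    if requested & {"dynamic_ddi", "report"}:
        outputs["dynamic_ddi"] = _stage_dynamic_ddi(
            config, outputs["static_ddi"], outputs["scaling"], outdir)
    if "report" in requested:
        outputs["report"] = _stage_report(
            outputs["static_ddi"], outputs.get("dynamic_ddi"),
            outputs.get("pbpk_dog"), outdir)

    manifest = {
        "package_version": __version__,
        "config": json.loads(config.model_dump_json()),
        "seed": config.seed,
        "outputs": {
            p.name: _sha256(p)
            for p in sorted(outdir.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return outputs
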