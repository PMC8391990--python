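"""End-to-end panel analysis: load → profile → forces → multivariate → write.

``run_study`` drives every stage on one panel and writes a fixed set of
tab-separated artifacts plus JSON summaries into the output directory,
together with the resolved configuration (for threshold auditability), a
stage-level run log and a manifest with a SHA-256 checksum per artifact.
Runs are deterministic: identical config + input give byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

from . import forces, multivariate_stats
from .codon_metrics import ReferenceWeights
from .composition import CompositionProfile
from .estimators import CodonUsageProfiler, RscuVectorizer
from .sequence_io import load_panel, write_panel
from .synthetic_data import SyntheticPanelSpec, generate_panel_with_truth, write_truth

__all__ = ["RunConfig", "run_study"]

_FLOAT_FMT = "%.6g"


@dataclass(frozen=True)
class RunConfig:
    """Resolved settings of one study run.

    Thresholds default to the conventional printed values: RSCU 0.6/1.6,
    dinucleotide odds 0.78/1.23, instability 40. ``gc3_policy`` selects
    the GC3 convention for the ENc–GC3 curve ("all" = every codon's
    third base, "synonymous" = Met/Trp/stop excluded).
    """

    input_fasta: Union[str, Path, None] = None
    synthetic_spec: SyntheticPanelSpec | None = None
    output_dir: Union[str, Path] = "codonusage_run"
    rscu_under: float = 0.6
    rscu_over: float = 1.6
    odds_under: float = 0.78
    odds_over: float = 1.23
    instability_threshold: float = 40.0
    cai_reference: Union[str, ReferenceWeights] = "panel"
    gc3_policy: str = "all"
    enc_curve_tolerance: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.input_fasta is None) == (self.synthetic_spec is None):
            raise ValueError(
                "exactly one of input_fasta / synthetic_spec must be set"
            )
        if self.gc3_policy not in ("all", "synonymous"):
            raise ValueError("gc3_policy must be 'all' or 'synonymous'")

    def as_text(self) -> str:
        lines = []
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, SyntheticPanelSpec):
                v = json.dumps(dataclasses.asdict(v), default=str)
            elif isinstance(v, ReferenceWeights):
                v = f"<ReferenceWeights:{v.reference_id}>"
            lines.append(f"{f.name} = {v}\n")
        return "".join(lines)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def _profiles_from_frame(profile: pd.DataFrame) -> list[CompositionProfile]:
    cols = [f.name for f in dataclasses.fields(CompositionProfile)]
    return [
        CompositionProfile(**{c: float(row[c]) for c in cols})
        for _, row in profile.iterrows()
    ]


def run_study(config: RunConfig) -> Path:
    """Run the full analysis; returns the output directory path.

    Raises on an empty accepted panel; any stage failure propagates with
    the stage name prepended.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = []

    def stage(name: str):
        log.append(f"stage: {name}")

    try:
        stage("load")
        if config.input_fasta is not None:
            panel, rejections = load_panel(config.input_fasta)
        else:
            panel, truth = generate_panel_with_truth(config.synthetic_spec)
            write_truth(truth, outdir / "truth.json")
            write_panel(panel, outdir / "panel.fasta")
            from .sequence_io import PanelRejectionReport

            rejections = PanelRejectionReport()
        rejections.to_tsv(outdir / "rejections.tsv")
        if not panel:
            raise ValueError("no sequences passed the inclusion filters")
        log.append(f"accepted {len(panel)} genes, rejected {len(rejections)}")

        stage("profile")
        profiler = CodonUsageProfiler(cai_reference=config.cai_reference)
        profile = profiler.fit_transform(panel)
        profile["unstable"] = profile["instability_index"] > config.instability_threshold
        _write_tsv(profile, outdir / "gene_profile.tsv")
        profiler.reference_weights_.to_tsv(outdir / "reference_weights.tsv")

        stage("rscu")
        rscu_matrix = RscuVectorizer().fit_transform(panel)
        _write_tsv(rscu_matrix, outdir / "rscu_matrix.tsv")
        classes = rscu_matrix.apply(
            lambda col: np.select(
                [col.isna(), col < config.rscu_under, col > config.rscu_over],
                ["MISSING", "UNDER", "OVER"],
                default="RANDOM",
            )
        )
        classes.index = rscu_matrix.index
        _write_tsv(classes, outdir / "rscu_classification.tsv")

        stage("dinucleotide")
        rho_cols = [c for c in profile.columns if c.startswith("rho_")]
        odds = profile[rho_cols].copy()
        for c in rho_cols:
            odds[c.replace("rho_", "class_")] = np.select(
                [odds[c].isna(), odds[c] < config.odds_under, odds[c] > config.odds_over],
                ["MISSING", "UNDER", "OVER"],
                default="NORMAL",
            )
        _write_tsv(odds, outdir / "dinucleotide_odds.tsv")

        stage("forces")
        profiles = _profiles_from_frame(profile)
        fit = forces.neutrality_fit(profiles)
        (outdir / "neutrality.json").write_text(
            json.dumps(dataclasses.asdict(fit), indent=2) + "\n"
        )
        parity = profile[["pr2_x", "pr2_y"]].rename(
            columns={"pr2_x": "x", "pr2_y": "y"}
        )
        _write_tsv(parity, outdir / "parity.tsv")
        (outdir / "parity_summary.json").write_text(
            json.dumps(forces.parity_summary(profiles), indent=2) + "\n"
        )
        gc3_col = "GC3" if config.gc3_policy == "all" else "gc3_synonymous"
        assessment = forces.enc_gc3_assessment(
            list(profile.index),
            (profile[gc3_col] / 100.0).tolist(),
            profile["enc"].tolist(),
            tolerance=config.enc_curve_tolerance,
            gc3_policy=config.gc3_policy,
        )
        _write_tsv(assessment.table, outdir / "enc_gc3.tsv")
        reg = forces.third_position_regressions(profiles)
        reg_df = pd.DataFrame(
            {n: dataclasses.asdict(r) for n, r in reg.items()}
        ).T.rename_axis("nucleotide")
        reg_df["mutational_force_pct"] = 100.0 * reg_df["r_squared"]
        _write_tsv(reg_df, outdir / "third_position_regressions.tsv")

        stage("pca")
        pca = multivariate_stats.pca_rscu(rscu_matrix)
        _write_tsv(pca.scores, outdir / "pca_scores.tsv")
        _write_tsv(pca.loadings, outdir / "pca_loadings.tsv")
        _write_tsv(
            pd.DataFrame(
                {"variance_pct": pca.variance_fraction},
                index=pca.loadings.columns,
            ).rename_axis("axis"),
            outdir / "pca_variance.tsv",
        )

        stage("correlations")
        gc_cols = ["GC", "GC1", "GC2", "GC3", "GC12", "cai59", "enc"]
        corr_gc = multivariate_stats.correlate(
            profile[gc_cols],
            pairs=[(a, b) for a in ["GC", "GC1", "GC2", "GC3", "GC12"] for b in ["cai59", "enc"]],
        )
        _write_tsv(corr_gc.set_index("variable_a"), outdir / "correlations_gc.tsv")
        comp3 = profile[["pA3", "pC3", "pG3", "pT3", "pA", "pC", "pG", "pT", "GC3", "GC"]]
        corr_third = multivariate_stats.correlate(
            comp3,
            pairs=[
                (f"p{n}3", f"p{m}") for n in "ACGT" for m in "ACGT"
            ]
            + [(f"p{n}3", "GC3") for n in "ACGT"]
            + [("GC3", "GC")],
        )
        _write_tsv(
            corr_third.set_index("variable_a"),
            outdir / "correlations_composition.tsv",
        )
        protein_cols = [
            "gravy", "aroma", "pi", "aliphatic_index", "hydrophobicity_pct",
            "instability_index", "n_acidic", "n_basic", "n_neutral",
        ]
        corr_protein = multivariate_stats.correlate(
            profile[protein_cols + ["cai18", "enc"]],
            pairs=[(p, t) for p in protein_cols for t in ("cai18", "enc")],
        )
        _write_tsv(
            corr_protein.set_index("variable_a"),
            outdir / "correlations_protein.tsv",
        )

        stage("finalize")
        (outdir / "resolved_config.txt").write_text(config.as_text())
        log_path = outdir / "run_log.txt"
        log_path.write_text("".join(f"{line}\n" for line in log))
        artifacts = sorted(
            p for p in outdir.iterdir() if p.is_file() and p.name != "manifest.json"
        )
        manifest = {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest() for p in artifacts
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    except Exception as err:  # annotate with the failing stage
        current = log[-1] if log else "startup"
        raise RuntimeError(f"pipeline failed at {current!r}: {err}") from err
    return outdir
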