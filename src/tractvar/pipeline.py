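"""End-to-end pipeline: scan -> census -> map -> spectra (-> ncp, structure).

A run is described by a validated :class:`RunConfig` (usually a YAML
file); outputs are tidy TSVs plus a JSON manifest recording the package
version, parameters and input checksums so a rerun with the same config
reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, asdict

import pandas as pd

from . import __version__
from . import ncp as ncp_mod
from . import spectra as spectra_mod
from . import structure as structure_mod
from .tracts import (IntervalSet, TractCensus, build_census, scan_fasta,
                     tracts_to_bed, tracts_to_frame)
from .variants import (ReferenceAccessor, assignments_to_frame, dedupe_variants,
                       map_variants, normalize_variants, read_vcf)

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    fasta: str | None = None
    vcf: str | None = None
    mask_bed: str | None = None
    midpoints_bed: str | None = None
    annotation_tsv: str | None = None
    step_params_tsv: str | None = None
    phosphate_tsv: str | None = None
    bridge_counts_tsv: str | None = None
    outdir: str = "tractvar_out"
    run_spectra: bool = True
    run_ncp: bool = False
    run_structure: bool = False
    loess_span: float = 0.100
    loess_degree: int = 3
    seed: int | None = None

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ConfigError(f"unknown config fields: {sorted(bad)}")
        return cls(**raw)

    def validate(self) -> None:
        if self.fasta is None:
            raise ConfigError("config field 'fasta' is required")
        checks = {
            "fasta": self.fasta, "vcf": self.vcf, "mask_bed": self.mask_bed,
            "midpoints_bed": self.midpoints_bed,
            "annotation_tsv": self.annotation_tsv,
            "step_params_tsv": self.step_params_tsv,
            "phosphate_tsv": self.phosphate_tsv,
            "bridge_counts_tsv": self.bridge_counts_tsv,
        }
        for name, path in checks.items():
            if path is not None and not os.path.exists(path):
                raise ConfigError(f"config field '{name}': file not found: {path}")
        if self.run_spectra and self.vcf is None:
            raise ConfigError("config field 'vcf' is required when run_spectra is enabled")
        if self.run_ncp and self.midpoints_bed is None:
            raise ConfigError("config field 'midpoints_bed' is required when run_ncp is enabled")
        if self.run_structure and self.step_params_tsv is None:
            raise ConfigError(
                "config field 'step_params_tsv' is required when run_structure is enabled"
            )


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict[str, str]:
    """Execute the configured stages; returns {output name: path}.

    Validation failures raise :class:`ConfigError` before anything is
    written.
    """
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)

    inputs = {
        k: v
        for k, v in asdict(config).items()
        if k.endswith(("fasta", "vcf", "_bed", "_tsv")) and v
    }
    params = asdict(config)
    params.pop("outdir")  # content must not depend on the output location
    manifest = {
        "tractvar_version": __version__,
        "parameters": params,
        "input_sha256": {k: _sha256(v) for k, v in inputs.items()},
    }
    manifest_hash = hashlib.sha256(
        json.dumps(manifest, sort_keys=True).encode()
    ).hexdigest()[:16]
    manifest["manifest_hash"] = manifest_hash
    outputs: dict[str, str] = {}

    def write(name: str, df: pd.DataFrame) -> None:
        path = os.path.join(config.outdir, name)
        with open(path, "w") as fh:
            fh.write(f"# tractvar manifest {manifest_hash}\n")
            df.to_csv(fh, sep="\t", index=False)
        outputs[name] = path

    logger.info("scanning %s", config.fasta)
    tracts = scan_fasta(config.fasta)
    tracts.sort(key=lambda t: (t.chrom, t.start))
    tracts_to_bed(tracts, os.path.join(config.outdir, "tracts.bed"))
    outputs["tracts.bed"] = os.path.join(config.outdir, "tracts.bed")

    mask = IntervalSet.read_bed(config.mask_bed) if config.mask_bed else None
    census = build_census(tracts, mask=mask)
    write("census.tsv", census.table)

    assignments = None
    if config.run_spectra:
        from pyfaidx import Fasta

        ref = ReferenceAccessor(Fasta(config.fasta, as_raw=True, sequence_always_upper=True))
        logger.info("normalizing variants from %s", config.vcf)
        variants = dedupe_variants(normalize_variants(read_vcf(config.vcf), ref))
        assignments = map_variants(tracts, variants, ref)
        write("assignments.tsv", assignments_to_frame(assignments))
        write("f_snv.tsv", spectra_mod.f_snv_table(assignments, census))
        write("positional_spectrum.tsv",
              spectra_mod.positional_spectrum(assignments, census).table)
        write("direction_bias.tsv", spectra_mod.direction_bias(assignments))
        write("slippage.tsv", spectra_mod.slippage_stats(assignments, census))
        write("indel_fractions.tsv", spectra_mod.indel_fractions(assignments, census))
        write("insertion_matrix.tsv",
              spectra_mod.insertion_position_matrix(assignments, census).table)

    if config.run_ncp:
        midpoints = ncp_mod.read_midpoints_bed(config.midpoints_bed)
        profile = ncp_mod.dyad_profile(tracts, midpoints, unit="bp")
        orient = ncp_mod.orientation_ratio_profile(tracts, midpoints, assignments)
        orient.smoothed = ncp_mod.smooth_profile(
            orient.ratio, orient.d, span=config.loess_span, degree=config.loess_degree
        )
        ann = ncp_mod.load_ncp_annotation(config.annotation_tsv)
        prof = profile.to_frame().merge(orient.to_frame(), on="d", suffixes=("", "_orient"))
        prof = prof.merge(ann, on="d", how="left")
        write("ncp_profile.tsv", prof)
        period, p_val = ncp_mod.estimate_period(profile.counts, profile.d,
                                                seed=config.seed)
        write("ncp_period.tsv",
              pd.DataFrame({"period_bp": [period], "p_value": [p_val]}))

    if config.run_structure:
        series = structure_mod.read_step_params(config.step_params_tsv)
        write(
            "v_step.tsv",
            pd.DataFrame(
                {"step_label": [s.label for s in series],
                 "v_step": [structure_mod.v_step(s) for s in series],
                 "n_frames": [s.n_frames for s in series]}
            ),
        )
        if config.phosphate_tsv:
            trace = structure_mod.read_phosphate_trace(config.phosphate_tsv)
            write("groove_width.tsv", structure_mod.groove_width(trace))
        if config.bridge_counts_tsv:
            counts = structure_mod.read_bridge_counts(config.bridge_counts_tsv)
            write("bridge_occupancy.tsv", structure_mod.bridge_occupancy(counts))

    with open(os.path.join(config.outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    outputs["manifest.json"] = os.path.join(config.outdir, "manifest.json")
    return outputs
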