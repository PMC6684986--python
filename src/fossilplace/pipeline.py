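"""End-to-end workflow: parsimony profile -> bootstrap -> Bayesian MCMC ->
filtered consensus-network splits -> human-readable summary.

One global seed deterministically derives independent per-stage seeds by
hashing the stage name, so a stage rerun in isolation reproduces its
in-pipeline result.  All outputs are plain text (TSV/JSON/NEXUS/YAML)
and byte-identical across reruns with the same config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
import yaml

from .matrices import read_nexus_matrix, validate_compatibility
from .mcmc import SamplerConfig, asdsf, combine_runs, mcmc_run, placement_posterior
from .parsimony import bootstrap_placements, placement_profile
from .splits import (filter_splits, render_split, splits_from_attachment,
                     write_splits_nexus)
from .trees import read_newick

__all__ = ["RunConfig", "run_all", "derive_seed"]

log = logging.getLogger("fossilplace")


def derive_seed(seed: int, stage: str) -> int:
    """Stage seed from the global seed by hashing the stage name."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


@dataclass(frozen=True)
class RunConfig:
    """Whole-workflow settings; the defaults reproduce the study design
    (1000 bootstrap replicates, 2 runs x 4 chains x 10^6 generations,
    25% burn-in, 15% split cutoff)."""

    matrix_path: str = ""
    backbone_path: str = ""
    fossil: str = "Dioonopsis"
    output_dir: str = "results"
    seed: int = 42
    n_bootstrap: int = 1000
    splits_cutoff: float = 0.15
    sampler: SamplerConfig = field(default_factory=SamplerConfig)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sampler = d.pop("sampler", {})
        return cls(sampler=SamplerConfig(**sampler), **d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(text))


def _write(path: Path, text: str) -> None:
    path.write_text(text)
    log.info("wrote %s", path)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_all(config: RunConfig) -> dict:
    """Run the full analysis; writes the report bundle into
    ``config.output_dir`` and returns the in-memory results.

    Outputs: placement profile TSV (steps per attachment edge with MP flag
    and bootstrap support), bootstrap and posterior split tables and
    SplitsTree NEXUS files, per-run MCMC trace TSVs, a posterior JSON with
    placement probabilities and the ASDSF, an effective-config YAML, and a
    plain-text summary."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    stage = "load"
    try:
        matrix = read_nexus_matrix(Path(config.matrix_path).read_text())
        backbone = read_newick(Path(config.backbone_path).read_text())
        report = validate_compatibility(matrix, backbone, config.fossil)
        if not report.ok:
            raise ValueError("; ".join(report.messages))
    except Exception as exc:
        log.error("stage %s failed: %s", stage, exc)
        raise StageError(stage, exc) from exc

    taxa = matrix.taxa
    results: dict = {"config": config}

    try:
        stage = "parsimony"
        profile = placement_profile(backbone, matrix, config.fossil)
        results["profile"] = profile
        log.info("parsimony: min %d steps over %d placements (%d MP)",
                 profile.min_steps, len(profile.edge_steps), len(profile.mp_edges))

        stage = "bootstrap"
        boot = bootstrap_placements(backbone, matrix, config.fossil,
                                    n_replicates=config.n_bootstrap,
                                    seed=derive_seed(config.seed, "bootstrap"))
        results["bootstrap"] = boot
        boot_splits = filter_splits(boot.split_support, config.splits_cutoff,
                                    n_source_trees=boot.n_replicates)
        results["bootstrap_splits"] = boot_splits

        rows = ["split\tsteps\tis_mp\tbootstrap_support"]
        for e in sorted(profile.edge_steps, key=sorted):
            rows.append("\t".join([
                render_split(e, taxa),
                str(profile.edge_steps[e]),
                "1" if e in profile.mp_edges else "0",
                repr(boot.placement_support[e]),
            ]))
        _write(out / "placement_profile.tsv", "\n".join(rows) + "\n")
        _write(out / "bootstrap_splits.nex", write_splits_nexus(boot_splits, taxa))
        _write(out / "bootstrap_splits.tsv", _splits_tsv(boot_splits, taxa))

        stage = "bayes"
        sampler = dataclasses.replace(config.sampler,
                                      seed=derive_seed(config.seed, "bayes"))
        traces = mcmc_run(backbone, matrix, config.fossil, sampler)
        results["traces"] = traces
        for i, run in enumerate(traces.runs, start=1):
            _write(out / f"trace_run{i}.tsv", _trace_tsv(run, traces, taxa))
        combined = combine_runs(traces)
        posterior = placement_posterior(combined)
        diag = asdsf(traces)
        results["posterior"] = posterior
        results["asdsf"] = diag
        log.info("bayes: ASDSF %.4f", diag)

        cache: dict = {}
        post_split_freqs: dict = {}
        for s in combined.samples:
            for split in splits_from_attachment(backbone, s.edge, config.fossil,
                                                _cache=cache):
                post_split_freqs[split] = (post_split_freqs.get(split, 0.0)
                                           + 1.0 / len(combined.samples))
        post_splits = filter_splits(post_split_freqs, config.splits_cutoff,
                                    n_source_trees=len(combined.samples))
        results["posterior_splits"] = post_splits
        _write(out / "posterior_splits.nex", write_splits_nexus(post_splits, taxa))
        _write(out / "posterior_splits.tsv", _splits_tsv(post_splits, taxa))
        _write(out / "posterior.json", json.dumps({
            "placement_posterior": {render_split(e, taxa): p
                                    for e, p in sorted(posterior.items(),
                                                       key=lambda kv: sorted(kv[0]))},
            "asdsf": diag,
            "n_samples": len(combined.samples),
        }, indent=2, sort_keys=True) + "\n")

        stage = "summary"
        _write(out / "summary.txt", _summary_text(config, taxa, profile, boot_splits,
                                                  post_splits, posterior, diag))
        _write(out / "effective_config.yaml", config.to_yaml())
    except StageError:
        raise
    except Exception as exc:
        log.error("stage %s failed: %s", stage, exc)
        raise StageError(stage, exc) from exc

    log.info("pipeline finished in %.1f s", time.time() - t0)
    return results


def _splits_tsv(splits, taxa) -> str:
    rows = ["split\tfrequency"]
    for s, f in sorted(splits.frequencies.items(), key=lambda kv: (-kv[1], sorted(kv[0]))):
        rows.append(f"{render_split(s, taxa)}\t{f!r}")
    return "\n".join(rows) + "\n"


def _trace_tsv(run, traces, taxa) -> str:
    header = ["generation", "attachment", "pendant_length", "alpha",
              "log_posterior"] + [f"len[{render_split(e, taxa)}]"
                                  for e in traces.edge_order]
    rows = ["\t".join(header)]
    for s in run.samples:
        rows.append("\t".join(
            [str(s.generation), render_split(s.edge, taxa),
             repr(s.pendant_length), repr(s.alpha), repr(s.log_posterior)]
            + [repr(x) for x in s.lengths]))
    return "\n".join(rows) + "\n"


def _summary_text(config, taxa, profile, boot_splits, post_splits,
                  posterior, diag) -> str:
    lines = [
        f"Fossil placement summary for {config.fossil!r}",
        "",
        f"Most parsimonious placement(s): {profile.min_steps} steps",
    ]
    for e in sorted(profile.mp_edges, key=sorted):
        lines.append(f"  MP edge: {render_split(e, taxa)}")
    lines.append("")
    lines.append("Step margin of every non-MP placement:")
    for e in sorted(profile.edge_steps, key=sorted):
        if e not in profile.mp_edges:
            lines.append(f"  +{profile.margin(e)}  {render_split(e, taxa)}")
    lines.append("")
    best = max(posterior.items(), key=lambda kv: kv[1])
    lines.append(f"Highest posterior placement: {render_split(best[0], taxa)} "
                 f"(p = {best[1]:.3f}); ASDSF = {diag:.4f}")
    lines.append("")
    for name, ws in (("bootstrap", boot_splits), ("posterior", post_splits)):
        lines.append(f"Two strongest {name} splits (cutoff {ws.cutoff:.0%}):")
        for s, f in ws.top(2):
            lines.append(f"  {f:.3f}  {render_split(s, taxa)}")
        lines.append("")
    return "\n".join(lines)
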