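"""End-to-end haplotype pipeline: variants -> consequences -> network ->
recombination -> protein screen, with all reports written to disk.

All data outputs are deterministic for a given configuration and input;
logging goes to standard error, machine-readable results to files.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import yaml

from . import network as net
from . import recombination as recomb
from . import screen as scr
from . import variants as var
from .domains import DomainMap
from .sequences import CodingSequence, read_cds_fasta, translate
from .simulate import make_reference

log = logging.getLogger("cyp75")

_KNOWN_KEYS = {
    "reference_fasta", "panel_fasta", "domain_map", "out_dir", "rule_index",
    "max_mismatch", "essential", "seed", "n_permutations", "max_breakpoints",
}


@dataclass
class PipelineConfig:
    reference_fasta: str | None = None
    panel_fasta: str | None = None
    domain_map: str | None = None
    out_dir: str = "cyp75_out"
    rule_index: int = 8
    max_mismatch: int = 2
    essential: list[str] | None = None
    seed: int = 0
    n_permutations: int = 999
    max_breakpoints: int = 2

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def resolve_inputs(self) -> tuple[CodingSequence, list[CodingSequence], DomainMap]:
        """Load reference, panel and domain map; fall back to the built-in
        synthetic panel when no paths are configured."""
        if self.reference_fasta is None or self.panel_fasta is None:
            from .simulate import make_paper_panel

            reference, domains = make_reference()
            panel, _ = make_paper_panel()
            return reference, panel, domains
        for key in ("reference_fasta", "panel_fasta", "domain_map"):
            value = getattr(self, key)
            if value is not None and not Path(value).exists():
                raise FileNotFoundError(f"{key}: {value}")
        reference = read_cds_fasta(self.reference_fasta)[0]
        panel = read_cds_fasta(self.panel_fasta)
        if self.domain_map is not None:
            domains = DomainMap.from_tsv(self.domain_map)
        else:
            _, domains = make_reference()
        return reference, panel, domains


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle; returns the summary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    reference, panel, domains = config.resolve_inputs()
    if not panel:
        raise net.NothingToNetworkError("nothing to network: empty panel")
    log.info("panel of %d haplotypes vs reference %s", len(panel), reference.id)

    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    calls = {hap.id: var.call_variants(hap, reference) for hap in panel}
    var.variants_to_tsv(calls, out / "variants.tsv")
    var.variants_to_vcf(calls, reference, out / "variants.vcf")
    timings["variants"] = time.perf_counter() - t0
    log.info("variants: %d calls", sum(map(len, calls.values())))

    t0 = time.perf_counter()
    reports = [var.predict_consequence(hap, reference, domains) for hap in panel]
    var.reports_to_json(reports, out / "consequences.json")
    var.reports_to_tsv(reports, out / "consequences.tsv")
    timings["consequences"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    matrix = net.encode_characters(panel, reference)
    closure = net.median_closure(matrix)
    graph = net.build_network(closure, matrix)
    net.write_network(
        graph, out / "network.gml", out / "network_edges.tsv", out / "network_nodes.tsv"
    )
    timings["network"] = time.perf_counter() - t0
    log.info("network: %d nodes (%d observed), %d edges",
             graph.number_of_nodes(), matrix.n_haplotypes, graph.number_of_edges())

    t0 = time.perf_counter()
    rec_reports = [
        r for r in recomb.scan_triplets(
            panel, reference, n_permutations=config.n_permutations, seed=config.seed
        )
        if r.minimal_breakpoints <= config.max_breakpoints
    ]
    recomb.reports_to_tsv(rec_reports, out / "recombination.tsv")
    timings["recombination"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    proteins = [translate(hap) for hap in panel]
    ref_protein = translate(reference)
    screen_records = scr.screen_proteome(
        proteins, ref_protein, domains,
        max_mismatch=config.max_mismatch, rule_index=config.rule_index,
        essential=config.essential,
    )
    scr.screen_to_tsv(screen_records, out / "screen.tsv")
    timings["screen"] = time.perf_counter() - t0

    class_tally: dict[str, int] = {}
    for r in reports:
        class_tally[r.functional_class] = class_tally.get(r.functional_class, 0) + 1
    recombinants = sorted(r.child for r in rec_reports if r.is_recombinant)
    summary = {
        "reference": reference.id,
        "n_haplotypes": len(panel),
        "n_observed_nodes": matrix.n_haplotypes,
        "functional_classes": dict(sorted(class_tally.items())),
        "n_non_functional": sum(
            v for k, v in class_tally.items() if k != var.FUNCTIONAL
        ),
        "recombinant_children": recombinants,
        "n_recombinants": len(recombinants),
        "hub_haplotype": net.hub_haplotype(graph),
        "n_passing_screen": sum(r.passed_filter for r in screen_records),
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")
    for stage, seconds in timings.items():
        log.info("stage %s: %.2f s", stage, seconds)
    return summary
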