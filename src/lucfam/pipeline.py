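"""End-to-end orchestration: simulate -> call -> classify -> stats -> tree -> annotate.

Produces, under an output directory, the per-stage artifacts plus a summary
report: a haplotype-by-sample evidence table, per-family diversity and
between-family divergence tables, McDonald-Kreitman tables, and a Newick
tree on synonymous distances.  Every random stage records its seed and all
effective parameter defaults are logged in the report header.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd

from . import famassign, hapcall, phylo, popgen, seqio, synthdata
from .core import SeqRecord, anchor_align, build_site_mask

DEFAULTS = {
    "posterior_threshold": 0.95,
    "min_freq": 0.15,
    "min_read_length": 151,
    "ts_tv_R": 2.0,
    "gamma_a": 1.0,
    "bootstrap_B": 1000,
    "mosaic_min_gain": 3,
}


def sim_config_from_dict(d: dict) -> synthdata.SimConfig:
    kw = dict(d)
    fams = [synthdata.FamilyConfig(**f) for f in kw.pop("families", [])]
    rs = synthdata.ReadSimConfig(**kw.pop("read_sim", {}))
    recs = [synthdata.RecombinantConfig(**r) for r in kw.pop("recombinants", [])]
    cfg = synthdata.SimConfig(read_sim=rs, recombinants=recs, **kw)
    if fams:
        cfg.families = fams
    return cfg


def paper_like_sim_config(seed: int = 0, samples: int = 3,
                          n_copies: int = 3) -> synthdata.SimConfig:
    """Three gene families with the study's divergence regime: a deep split
    (Ks ~ 0.8) and a younger duplication (Ks ~ 0.16), silent diversity
    ~0.15 within families and strong purifying selection (omega = 0.05)."""
    return synthdata.SimConfig(
        seed=seed,
        families=[
            synthdata.FamilyConfig(name="F1", n_copies=n_copies,
                                   target_ks_within=0.15, omega=0.05),
            synthdata.FamilyConfig(name="F2", parent="F1", target_ks_between=0.8,
                                   n_copies=n_copies, target_ks_within=0.15,
                                   omega=0.05),
            synthdata.FamilyConfig(name="F3", parent="F2", target_ks_between=0.16,
                                   n_copies=n_copies, target_ks_within=0.15,
                                   omega=0.05),
        ],
        samples=samples,
    )


def run_end_to_end(cfg: synthdata.SimConfig, outdir, bootstrap_B: int = 1000,
                   with_clones: bool = True) -> dict:
    """Run the full synthetic pipeline; returns the in-memory result bundle."""
    out = seqio.ensure_dir(outdir)
    result: dict = {"seed": cfg.seed, "defaults": dict(DEFAULTS)}

    # --- simulate ---------------------------------------------------------
    truth = synthdata.simulate_family_set(cfg)
    reads_by_sample, read_map = synthdata.simulate_reads(truth)
    clones, clone_map = (synthdata.simulate_clones(truth)
                         if with_clones else ([], {}))
    seqio.write_fasta(
        [SeqRecord(id=h.name, nucleotides=h.sequence) for h in truth.haplotypes],
        out / "truth_haplotypes.fasta")
    seqio.write_exon_table({"simlocus": truth.annotation}, out / "exons.tsv")
    for sid, reads in reads_by_sample.items():
        seqio.write_fastq(reads, out / f"reads_{sid}.fastq")
    if clones:
        seqio.write_fasta(clones, out / "clones.fasta")
    pd.DataFrame([(r, *src) for r, src in sorted(read_map.items())],
                 columns=["read", "source", "strand"]).to_csv(
        out / "read_to_source.tsv", sep="\t", index=False)
    result["truth"] = truth

    # --- call -------------------------------------------------------------
    amp = cfg.read_sim.amplicon or (1, cfg.locus_length)
    first_family = cfg.families[0].name
    ref = SeqRecord(id="simlocus_amplicon",
                    nucleotides=truth.family_founders[first_family][amp[0] - 1:amp[1]],
                    evidence_source="REF")
    cands = hapcall.call_samples(reads_by_sample, ref, eps=max(cfg.read_sim.sub_rate, 1e-4))
    accepted, audit = hapcall.apply_validation_cascade(cands, clones, ref)
    registry = hapcall.build_registry(accepted, clones, ref, locus="simlocus")
    pd.DataFrame([dataclasses.asdict(a) for a in audit]).to_csv(
        out / "cascade_audit.tsv", sep="\t", index=False)
    pd.DataFrame([{
        "sequence": e.sequence[:40], "sources": "+".join(sorted(e.sources)),
        "clones": e.clone_count, "samples": len(e.samples_observed),
        **{f"reads_{s}": n for s, n in sorted(e.read_counts.items())}}
        for e in registry.entries]).to_csv(out / "registry.tsv", sep="\t", index=False)
    result["accepted"] = accepted
    result["registry"] = registry

    # --- classify ---------------------------------------------------------
    fam_names = [f.name for f in cfg.families]
    unique_rows: dict[str, str] = {h.name: h.sequence for h in truth.haplotypes
                                   if h.family != "recombinant"}
    mosaic_rows = {h.name: h.sequence for h in truth.haplotypes
                   if h.family == "recombinant"}
    classified: dict[str, str] = {}
    mosaics: list[str] = []
    if len(fam_names) >= 2:
        diags = []
        for i, fa in enumerate(fam_names):
            for fb in fam_names[i + 1:]:
                diags.append(famassign.find_diagnostic_sites(
                    truth.family_rows(fa), truth.family_rows(fb), fa, fb))
        for name, row in {**unique_rows, **mosaic_rows}.items():
            votes: dict[str, int] = {}
            is_mosaic = False
            for diag in diags:
                label, score, _ = famassign.assign_family(row, diag)
                votes[label] = votes.get(label, 0) + 1
                call = famassign.detect_mosaic(row, diag,
                                               min_gain=DEFAULTS["mosaic_min_gain"])
                if call.evaluable and call.is_mosaic:
                    is_mosaic = True
            if is_mosaic:
                mosaics.append(name)
                classified[name] = "mosaic"
            else:
                classified[name] = max(votes, key=lambda k: (votes[k], k))
        pd.DataFrame([{"haplotype": n, "label": l} for n, l in classified.items()]
                     ).to_csv(out / "classification.tsv", sep="\t", index=False)
    else:
        classified = {h.name: h.family for h in truth.haplotypes}
    result["classified"] = classified
    result["mosaics"] = mosaics

    # --- stats (mosaic-flagged haplotypes excluded by default) -----------
    ref_full = SeqRecord(id="simref",
                         nucleotides=truth.family_founders[first_family],
                         evidence_source="REF")
    keep = [h for h in truth.haplotypes
            if h.family != "recombinant" and h.name not in mosaics]
    aln = anchor_align([SeqRecord(id=h.name, nucleotides=h.sequence) for h in keep],
                       ref_full, free_end_gaps=False)
    mask = build_site_mask(aln, truth.annotation)
    rows_by_fam: dict[str, list[str]] = {}
    for h, m in zip(keep, aln.members):
        rows_by_fam.setdefault(h.family, []).append(m.nucleotides)

    div_rows = []
    for fam, rows in rows_by_fam.items():
        if len(rows) < 2:
            continue
        s = popgen.summarize_diversity(rows, mask)
        div_rows.append({"family": fam, "n": s.n, "S": s.S, "Hd": s.Hd,
                         "pi_silent": s.pi_silent, "pi_nonsyn": s.pi_nonsyn,
                         "tajima_D": s.tajima_D})
    pd.DataFrame(div_rows).to_csv(out / "diversity.tsv", sep="\t", index=False)
    result["diversity"] = div_rows

    ks_rows = []
    mk_rows = []
    fams = sorted(rows_by_fam)
    for i, fa in enumerate(fams):
        for fb in fams[i + 1:]:
            d = popgen.divergence(rows_by_fam[fa], rows_by_fam[fb], mask,
                                  labels=(fa, fb))
            ks_rows.append({"family_a": fa, "family_b": fb, "Ka": d.Ka, "Ks": d.Ks,
                            "Ka_over_Ks": d.Ka_over_Ks})
            if len(rows_by_fam[fa]) >= 2:
                mk = popgen.mk_test(rows_by_fam[fa], rows_by_fam[fb], mask)
                mk_rows.append({"ingroup": fa, "outgroup": fb, "Pn": mk.Pn,
                                "Ps": mk.Ps, "Dn": mk.Dn, "Ds": mk.Ds,
                                "fisher_p": mk.fisher_p, "NI": mk.NI})
    pd.DataFrame(ks_rows).to_csv(out / "divergence.tsv", sep="\t", index=False)
    pd.DataFrame(mk_rows).to_csv(out / "mk.tsv", sep="\t", index=False)
    result["divergence"] = ks_rows
    result["mk"] = mk_rows

    # --- tree -------------------------------------------------------------
    labels = [h.name for h in keep]
    tree = phylo.bootstrap_support([m.nucleotides for m in aln.members], labels,
                                   mask, B=bootstrap_B, seed=cfg.seed)
    newick = phylo.write_newick(tree)
    (out / "tree.nwk").write_text(newick + "\n")
    result["tree"] = tree
    result["newick"] = newick

    # --- report -----------------------------------------------------------
    lines = ["# lucfam pipeline report", f"seed: {cfg.seed}"]
    lines += [f"{k}: {v}" for k, v in DEFAULTS.items()]
    if not with_clones:
        lines.append("note: no clones supplied; indel/stop PCS exceptions disabled")
    lines.append(f"accepted haplotypes: {len(accepted)}")
    lines.append(f"mosaic haplotypes removed: {sorted(mosaics)}")
    lines.append("diversity: " + repr(div_rows))
    lines.append("divergence: " + repr(ks_rows))
    lines.append("mk: " + repr(mk_rows))
    lines.append("tree: " + newick)
    (out / "report.txt").write_text("\n".join(lines) + "\n")
    return result
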