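"""Regenerate the packaged registry data files (maintainer utility).

Writes templates.tsv / annotations.tsv / clusters.tsv under
src/igstrand/data/.  The template roster transcribes the published
reference set of Ig-fold topo-structural variants (surface receptors,
cytoplasmic and nuclear proteins); three rows marked "supplement" are
synthetic additions that bring the roster to its documented size of 55.
Strand annotations are derived from each cluster's idealized topology spec,
so they are consistent with the synthetic coordinates the registry
generates at load time.
"""

from __future__ import annotations

from pathlib import Path

from igstrand.topologies import TOPOLOGIES

OUT = Path(__file__).resolve().parent.parent / "src" / "igstrand" / "data"

# template_id, protein, ig_type, template_class, scop, pdb_id, chain, cluster, topology, comment
ROSTER = [
    # cluster 1: V-set (Ig)
    ("CD2_1hnfA_human_V-n1", "CD2", "IgV", "Ig", "b.1.1.1", "1hnf", "A", 1, "igv", ""),
    ("CD28_1yjdC_human_V", "CD28", "IgV", "Ig", "b.1.1.1", "1yjd", "C", 1, "igv", ""),
    ("CD8a_1cd8A_human_V", "CD8a", "IgV", "Ig", "b.1.1.1", "2atp", "A", 1, "igv", ""),
    ("FAB-HEAVY_5esv_V-n1", "FAB-VH", "IgV", "Ig", "b.1.1.1", "5esv", "C", 1, "igv", ""),
    ("FAB-LIGHT_5esv_V-n1", "FAB-VL", "IgV", "Ig", "b.1.1.1", "5esv", "D", 1, "igv", ""),
    ("ICOS_6x4gA_human_V", "CD278 (ICOS)", "IgV", "Ig", "b.1.1.1", "6x4g", "A", 1, "igv", ""),
    ("LAG3_7tzgD_human_V-n1", "LAG3", "IgV", "Ig", "Unk.", "7tzg", "D", 1, "igv", ""),
    ("PD1_4zqkB_human_V", "CD279 (PD1)", "IgV", "Ig", "b.1.1.1", "4zqk", "B", 1, "igv", ""),
    ("PDL1_4z18B_human_V-n1", "CD274 (PDL1)", "IgV", "Ig", "b.1.1.1", "4z18", "B", 1, "igv", ""),
    ("VNAR_1t6vN_shark_V", "VNAR", "IgV", "Ig", "b.1.1.1", "1t6v", "N", 1, "igv", ""),
    ("Zuppl_IgV_synth", "synthetic V-set supplement", "IgV", "Ig", "n/a", "", "", 1, "igv", "supplement"),
    # cluster 2: C1-set (Ig)
    ("B2Microglobulin_7phrL_human_C1", "B2-Microglobulin", "IgC1", "Ig", "b.1.1.2", "7phr", "L", 2, "igc1", ""),
    ("CD3d_6jxrd_human_C1", "CD3d", "IgC1", "Ig", "b.1.1.4", "6jxr", "d", 2, "igc1", ""),
    ("CD3e_6jxrf_human_C1", "CD3e", "IgC1", "Ig", "b.1.1.4", "6jxr", "f", 2, "igc1", ""),
    ("FAB-HEAVY_5esv_C1-n2", "FAB-CH1", "IgC1", "Ig", "b.1.1.2", "5esv", "C", 2, "igc1", ""),
    ("FAB-LIGHT_5esv_C1-n2", "FAB-CL1", "IgC1", "Ig", "b.1.1.2", "5esv", "D", 2, "igc1", ""),
    ("LAG3_7tzgD_human_C2-n2", "LAG3", "IgC1", "Ig", "Unk.", "7tzg", "D", 2, "igc1", ""),
    ("MHCIa_7phrH_human_C1", "MHCI alpha", "IgC1", "Ig", "b.1.1.2", "7phr", "H", 2, "igc1", ""),
    ("Siglec3_5j0bB_human_C1-n2", "Siglec-3 CD33", "IgC1", "Ig", "Unk.", "5j0b", "B", 2, "igc1", ""),
    # cluster 3: I-set (Ig)
    ("BTLA_2aw2A_human_Iset", "BTLA", "IgI", "Ig", "b.1.1.4", "2aw2", "A", 3, "igi", ""),
    ("Contactin1_3s97C_human_Iset-n2", "Contactin1", "IgI", "Ig", "b.1.1.0", "3s97", "C", 3, "igi", ""),
    ("JAM1_1nbqA_human_Iset-n2", "JAM1", "IgI", "Ig", "b.1.1.4", "1nbq", "A", 3, "igi", ""),
    ("Palladin_2dm3A_human_Iset-n1", "Palladin", "IgI", "Ig", "b.1.1.4", "2dm3", "A", 3, "igi", ""),
    ("Titin_4uowM_human_Iset-n152", "Titin", "IgI", "Ig", "Unk.", "4uow", "M", 3, "igi", ""),
    ("Zuppl_IgI_synth", "synthetic I-set supplement", "IgI", "Ig", "n/a", "", "", 3, "igi", "supplement"),
    # cluster 4: C2-set (Ig)
    ("CD19_6al5A_human_C2orV-n1", "CD19", "other-Ig", "Ig", "Unk.", "6al5", "A", 4, "igc2", ""),
    ("CD2_1hnfA_human_C2-n2", "CD2", "IgC2", "Ig", "b.1.1.3", "1hnf", "A", 4, "igc2", ""),
    ("CD3g_6jxrg_human_C2", "CD3g", "IgC2", "Ig", "b.1.1.4", "6jxr", "g", 4, "igc2_gplus", "G+ strand"),
    # cluster 5: FN3 (Ig-like)
    ("Contactin1_2ee2A_human_FN3-n9", "Contactin1", "IgFN3", "Ig-like", "b.1.2.0", "2ee2", "A", 5, "fn3", ""),
    ("GHR_1axiB_human_FN3-n1", "GHR", "IgFN3", "Ig-like", "b.1.2.1", "1axi", "B", 5, "fn3", ""),
    ("IL6Rb_1bquB_human_FN3-n2", "CD130 (IL6R-beta)", "IgFN3", "Ig-like", "b.1.2.1", "1bqu", "B", 5, "fn3", ""),
    ("IL6Rb_1bquB_human_FN3-n3", "CD130 (IL6R-beta)", "IgFN3", "Ig-like", "b.1.2.1", "1bqu", "B", 5, "fn3", ""),
    ("InsulinR_8guyE_human_FN3-n1", "Insulin Receptor", "IgFN3", "Ig-like", "b.1.2.1", "8guy", "E", 5, "fn3", ""),
    ("InsulinR_8guyE_human_FN3-n2", "Insulin Receptor", "IgFN3", "Ig-like", "b.1.2.1", "8guy", "E", 5, "fn3", ""),
    ("Sidekick2_1wf5A_human_FN3-n7", "Sidekick-2", "IgFN3", "Ig-like", "b.1.2.1", "1wf5", "A", 5, "fn3", ""),
    ("Zuppl_FN3_synth", "synthetic FN3 supplement", "IgFN3", "Ig-like", "n/a", "", "", 5, "fn3", "supplement"),
    # cluster 6: FN3-like (Ig-like)
    ("C3_2qkiD_human_n1", "C3 Complement", "IgFN3-like", "Ig-like", "b.1.29.2", "2qki", "D", 6, "fn3_like", ""),
    ("NaCaExchanger_2fwuA_dog_n2", "NaCa Exchanger", "IgFN3-like", "Ig-like", "b.1.27.1", "2fwu", "A", 6, "fn3_like", ""),
    # cluster 7: cadherin (Ig-like)
    ("ECadherin_4zt1A_human_n2", "E-Cadherin", "other-Ig", "Ig-like", "b.1.6.1", "4zt1", "A", 7, "cadherin", ""),
    # cluster 8
    ("NaKATPaseTransporterBeta_2zxeB_spurdogshark", "NaK ATPase Transporter-Beta", "other-Ig", "Ig-like", "b.1.32.1", "2zxe", "B", 8, "igc1_short", ""),
    # cluster 9
    ("RBPJ_6py8C_human_Unk-n1", "RBPJ", "other-Ig", "Ig-like", "Unk.", "6py8", "C", 9, "sandwich_min", ""),
    ("RBPJ_6py8C_human_Unk-n2", "RBPJ", "other-Ig", "Ig-like", "Unk.", "6py8", "C", 9, "sandwich_min", ""),
    # cluster 10
    ("ASF1A_2iijA_human", "ASF-1A Histone Chaperone", "IgFN3-like", "Ig-extended", "b.1.22.1", "2iij", "A", 10, "barrel_wide", ""),
    ("MPT63_1lmiA_bacteria", "MPT63", "IgFN3-like", "Ig-extended", "b.1.19.1", "1lmi", "A", 10, "barrel_wide", ""),
    # cluster 11: arrestin-like extended (A-, E+)
    ("BArrestin1_4jqiA_rat_n1", "B-Arrestin-1", "IgFN3-like", "Ig-extended", "b.1.18.11", "4jqi", "A", 11, "arrestin", "A-/E+ strands"),
    ("TEAD1_3kysC_human", "TEAD1 (TEF1)", "IgFN3-like", "Ig-extended", "b.1.18.26", "3kys", "C", 11, "arrestin", ""),
    # cluster 12: lamin tail domain (A-, E+)
    ("LaminAC_1ifrA_human", "Lamin-A/C", "other-Ig", "Ig-extended", "b.1.16.1", "1ifr", "A", 12, "lamin", "A- strand 14xx"),
    # cluster 13
    ("CoAtomerGamma1_1r4xA_human", "CoAtomer-Gamma-1", "other-Ig", "Ig-extended", "b.1.10.3", "1r4x", "A", 13, "ext_twist", ""),
    ("Endo-14-BetaXylanase10A_1i8aA_bacteria_n4", "Endo-1,4-Beta-Xylanase-A", "other-Ig", "Ig-extended", "b.1.9.2", "1i8a", "A", 13, "ext_twist", ""),
    # cluster 14
    ("CuZnSuperoxideDismutase_1hl5C_human", "CuZn Superoxide Dismutase", "IgFN3-like", "Ig-extended", "b.1.8.2", "1hl5", "C", 14, "ext_neat", ""),
    ("IsdA_2iteA_bacteria", "IsdA NEAT domain", "other-Ig", "Ig-extended", "b.1.28.1", "2ite", "A", 14, "ext_neat", "A- strand"),
    ("TP34_2o6cA_bacteria", "TP34", "other-Ig", "Ig-extended", "b.1.33.1", "2o6c", "A", 14, "ext_neat", ""),
    # cluster 15: extended V (A-, G+)
    ("VISTA_6oilA_human_V", "VISTA (VSIR)", "IgV", "Ig-extended", "b.1.1.1", "6oil", "A", 15, "ext_gplus", "A-/G+ strands"),
    # cluster 16: extended with A-, A+ and G+ insertions
    ("ORF7a_1xakA_virus", "ORF7a", "other-Ig", "Ig-like", "b.1.24.1", "1xak", "A", 16, "ext_full", ""),
    ("TP47_1o75A_bacteria", "Tp47 Lipoprotein", "other-Ig", "Ig-like", "b.1.20.1", "1o75", "A", 16, "ext_full", ""),
]


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    assert len(ROSTER) == 55, len(ROSTER)
    assert len({row[0] for row in ROSTER}) == 55
    clusters = sorted({row[7] for row in ROSTER})
    assert clusters == list(range(1, 17)), clusters

    with open(OUT / "templates.tsv", "w") as fh:
        fh.write(
            "template_id\tprotein\tig_type\ttemplate_class\tscop\tpdb_id\tchain\tcluster_id\ttopology\tcomment\n"
        )
        for tid, prot, igt, cls, scop, pdb, chain, cid, topo, comment in ROSTER:
            fh.write(f"{tid}\t{prot}\t{igt}\t{cls}\t{scop}\t{pdb}\t{chain}\t{cid}\t{topo}\t{comment}\n")

    with open(OUT / "annotations.tsv", "w") as fh:
        fh.write("template_id\tletter\ti_digit\tj_digit\tstart\tend\tanchor\tcomment\n")
        for tid, *_rest in ROSTER:
            topo = _rest[7]
            spec = TOPOLOGIES[topo]
            for strand, a, b in spec.strand_ranges():
                fh.write(
                    f"{tid}\t{strand.letter}\t{strand.i_digit}\t{strand.j_digit}\t"
                    f"{a + 1}\t{b + 1}\t{a + 1 + strand.anchor_offset}\t"
                    "idealized mid-strand anchor\n"
                )

    by_cluster: dict[int, list[str]] = {}
    for row in ROSTER:
        by_cluster.setdefault(row[7], []).append(row[0])
    with open(OUT / "clusters.tsv", "w") as fh:
        fh.write("cluster_id\trepresentative_id\tn_members\n")
        for cid in sorted(by_cluster):
            members = sorted(by_cluster[cid])
            fh.write(f"{cid}\t{members[0]}\t{len(members)}\n")
    print(f"wrote registry data for {len(ROSTER)} templates, {len(by_cluster)} clusters -> {OUT}")


if __name__ == "__main__":
    main()
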