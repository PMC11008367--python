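"""Regenerate the packaged catalog data files.

Writes, for every two-component catalog topology:
  * ``data/diagrams/<name>.txt``  -- the minimal planar diagram (crossing
    list with Wirtinger arcs, signs and component labels) extracted from
    the canonical projection of the ideal embedding;
  * ``data/conformations/<name>_N120.xyz`` -- the N = 120 bead
    realization of the ideal embedding.

Run from the repository root:  python scripts/make_catalog_data.py
"""

from pathlib import Path

from linkedrings import catalog
from linkedrings.io import write_xyz

DATA = Path(__file__).resolve().parent.parent / "src" / "linkedrings" / "data"


def main() -> None:
    (DATA / "diagrams").mkdir(parents=True, exist_ok=True)
    (DATA / "conformations").mkdir(parents=True, exist_ok=True)
    for name in catalog.link_ids():
        diagram = catalog._diagram_from_curves(
            name, list(catalog.ideal_curves(name)))
        safe = name.replace("^", "c").replace("_", "-")
        catalog.save_diagram(diagram, DATA / "diagrams" / f"{safe}.txt")
        conf = catalog.catalog_conformation(name, 120)
        write_xyz(DATA / "conformations" / f"{safe}_N120.xyz", conf,
                  comment=f"{name} ideal embedding, N=120 beads per ring")
        print(name, diagram.n_c, (diagram.n_self, diagram.n_mutual))


if __name__ == "__main__":
    main()
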