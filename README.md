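# halfchannel

Trajectory analyses for proton-transfer-chain integrity and hydration of the
inlet proton half-channel in the bacterial F<sub>o</sub>F<sub>1</sub>-ATP
synthase *a*-subunit.

## The problem

The membrane factor F<sub>o</sub> of ATP synthase moves protons through two
half-channels in the *a*-subunit. In *E. coli*, the inlet half-channel
narrows into a bottleneck near the key c-ring residue cD61, lined by a chain
of conserved polar residues (aE219, aD119, aH245, aN214, aQ252) and three
recurrent structural water-cluster sites: W1 near cD61, and W2/W3 between
aH245 and aN214. A proton can only traverse the bottleneck while polar
side-chain atoms and water oxygens form a continuous network of
hydrogen-bond-length contacts (heavy-atom distance ≤ 3 Å) from the gate to
cD61. Point mutations of the chain residues reshape local hydration and can
sever this network, which is how single substitutions block the whole
enzyme.

This package implements the analyses needed to assess that failure mode on
molecular-dynamics trajectories of wild-type and mutant systems, for
structural biologists and simulators studying proton translocation:

* **Stability battery** — backbone RMSD (Kabsch superposition), per-residue
  RMSF (two-pass fit to the mean structure), mass-weighted radius of
  gyration *R*<sub>g</sub>, Shrake–Rupley solvent-accessible surface area,
  and intramolecular hydrogen-bond counts; plus summarization of per-system
  stability tables.
* **Hydration clusters** — per-frame water counts in the W1 and W2/W3
  regions, occupancy (% of frames with ≥ 1 water) and capacity (probability
  distribution of the water count).
* **Transfer-chain connectivity** — a per-frame graph with polar side-chain
  atoms and zone waters as nodes and donor–acceptor pairs within 3 Å as
  edges; the chain verdict (*preserved*/*interrupted*) comes from the
  fraction of frames with a source→sink path.
* **Side-chain dynamics** — classification of a side chain's stable spatial
  positions (SP1–SP3) by clustering its terminal-atom position in a local
  backbone frame, gate-contact fractions (e.g. aR140 on aD119), and
  Cα–Cα distance distributions.
* **Membrane bookkeeping** — PE/CL class percentages and charge balance of
  the simulated bilayer composition.
* **Synthetic generator** — toy half-channel systems with *known ground
  truth* (water schedules, side-chain mode labels, per-frame connectivity),
  so every stage is verifiable without running MD. Ten packaged fixtures
  (wild type + nine substitutions) encode the qualitative hydration
  outcomes of the studied mutants.

Trajectories are read as multi-model PDB (mandatory dialect) or DCD
(optional, via MDAnalysis); scenarios are YAML; results are CSV/JSON.

## Worked example

Run the numbered analysis scripts from the repository root (each is a thin
driver over the library; outputs land in `results/`):

```sh
python analysis/01_generate_fixtures.py
python analysis/05_chain_verdicts.py
```

The verdict script prints, for each system, the percent of frames with a
continuous source→sink hydrogen-bond path and any canonical-chain segments
never bridged in any frame:

```
WT             preserved    79.2%  -
aE219G         preserved    67.3%  aE219-aD119
aE219Q         preserved    70.0%  -
aH245G         interrupted   0.0%  aD119-aH245;aH245-W2/W3;W2/W3-aN214
aH245S         preserved    86.5%  -
aH245Y         interrupted   0.0%  aN214-W1;W1-cD61
aE219H/aH245E  preserved    91.0%  -
aN214L         interrupted   0.0%  W2/W3-aN214;aN214-W1
aN214H         preserved    76.8%  -
aQ252L         preserved    86.5%  -

interrupted: ['aH245G', 'aH245Y', 'aN214L']
```

Reading this: the wild-type chain is connected in 79.2% of frames (it needs
both W1 and W2/W3 occupied simultaneously). Replacing histidine 245 with
glycine removes the relay side chain *and* dries out W2/W3, so no frame has
a complete path; the tyrosine substitution keeps W2/W3 but blocks water
from reaching W1, so cD61 can never be protonated; the leucine substitution
at 214 removes the relay between W2/W3 and W1. The polar serine
substitution at 245 keeps the chain intact through a wetter W2/W3 — the
same qualitative picture as the mutant simulations the fixtures encode.
(`aE219G` stays *preserved* while showing a broken `aE219-aD119` segment:
the glycine has no polar side chain, but the source of the analyzed chain
is the unmutated gate residue aD119, so the path does not need that
segment.)

The same systems via the CLI:

```sh
halfchannel generate --out scratch/fx --seed 11 --frames 600
halfchannel analyze --scenario scratch/fx/aH245G.yaml \
    --trajectory scratch/fx/aH245G.pdb --out scratch/aH245G --seed 1
# -> verdict[aH245G] = interrupted
halfchannel summarize        # packaged stability-table summary (JSON)
```

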