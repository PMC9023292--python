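# Default donor-acceptor contact maps for the cited decoding-center
# structures.  The source distance sets label hydrogen bonds 1, 1', 2, 3
# without printing atom names, so the atom identities below are
# RECONSTRUCTIONS of the canonical type-I A-minor geometry (adenosine
# N1/N3/O2' against the minor-groove edge and riboses of the first base
# pair).  Chain ids follow the deposited author naming of each entry and
# may need adjustment against a local copy; edit freely -- these maps are
# data, not code.  Residue numbering is author numbering (E. coli 16S
# numbering for h44 residues where applicable).
version: "1.0"
maps:
  5wfk:
    note: >
      A36-C1 mismatch at the first codon position: no base pair forms, so
      A1493 makes no hydrogen bond with the minor groove.  Advisory map:
      intentionally empty.
    contacts: []
  5uyp:
    note: >
      G35-U2 mismatch structure; A1493 binds the minor groove of the
      A36-U1 pair (three bonds, none optimal).  Reconstruction.
    contacts:
      - label: "1"
        donor: {chain: "a", resi: 1493, atom: "O2'"}
        acceptor: {chain: "w", resi: 36, atom: "O2'"}
      - label: "2"
        donor: {chain: "a", resi: 1493, atom: "N3"}
        acceptor: {chain: "v", resi: 1, atom: "O2'"}
      - label: "3"
        donor: {chain: "a", resi: 1493, atom: "N1"}
        acceptor: {chain: "v", resi: 1, atom: "O2"}
  5uyl:
    note: >
      Cognate complex in the sampling state; A1493 type-I A-minor on the
      A36-U1 pair (three bonds).  Reconstruction.
    contacts:
      - label: "1"
        donor: {chain: "a", resi: 1493, atom: "O2'"}
        acceptor: {chain: "w", resi: 36, atom: "O2'"}
      - label: "2"
        donor: {chain: "a", resi: 1493, atom: "N3"}
        acceptor: {chain: "v", resi: 1, atom: "O2'"}
      - label: "3"
        donor: {chain: "a", resi: 1493, atom: "N1"}
        acceptor: {chain: "v", resi: 1, atom: "O2"}
  1xnq:
    note: >
      X-ray 30S complex with a G-C pair at the first position; the
      guanine N2 amino group adds the fourth (1') hydrogen bond.
      Reconstruction.
    contacts:
      - label: "1"
        donor: {chain: "A", resi: 1493, atom: "O2'"}
        acceptor: {chain: "A", resi: 36, atom: "O2'"}
      - label: "1'"
        donor: {chain: "A", resi: 36, atom: "N2"}
        acceptor: {chain: "A", resi: 1493, atom: "O2'"}
      - label: "2"
        donor: {chain: "A", resi: 1493, atom: "N3"}
        acceptor: {chain: "A", resi: 1, atom: "O2'"}
      - label: "3"
        donor: {chain: "A", resi: 1493, atom: "N1"}
        acceptor: {chain: "A", resi: 1, atom: "O2"}
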