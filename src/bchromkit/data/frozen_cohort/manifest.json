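{
  "b_sequence_length": 30000,
  "n_contigs": 40,
  "n_truth_variants": 32,
  "sha256": {
    "b_contigs_fa": "886eade648ff453e5442bbdf628865741c56a99a4de31b313adfb2967ea1dbbf",
    "b_sequence": "3d5debde87618736e4683a5bc1c11bca71c01d3f2c0cee0779f09dd800dadee3",
    "ct_table_csv": "98ca12b6f4cf38c4a294ef14dc08f79044d4535d687511826849a3c12d067b39",
    "reads_0B_fastq": "a40cd04a145638e1f2cf34f2430130b1bf911324aa5548ac9df5265b64b10002",
    "reads_1B_fastq": "2d916aafc5871a4a1df3db1c0bd12affda6e2944e9f442a70239277b63aee724",
    "reads_2B_fastq": "0a29368ec398cdc3f09f54ec70bc459a112b7e99bf0dae825c8ddcf4307016cb",
    "reference_fa": "f5071612a856f6947d1473baf9602414520ae618d256c46cf7122fdf95e0ed1a"
  }
}
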