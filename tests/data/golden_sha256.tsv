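# sha256 of pipeline outputs on the seed-7 synthetic fixture
assignments_VEL1_6WT0.tsv	9c599e9e22309c0376a4d7a284d28c0459822f26e3ad8d4104459de60474749b
assignments_VEL1_NV.tsv	1c71ab4c69ba348f64eb289fbde9f41adabebdec0625be27280869e82e032e2b
assignments_VIN3_6WT0.tsv	77da885e9d3181a59cfc6058eb0355b77624e8a923cba812fdb7bd19cf78886d
assignments_VIN3_NV.tsv	d8d2218ee5b037fa8f0670688f37bf1b6a7e4038837713d2888a0723f96821c2
consensus_VEL1_6WT0.bed	0c9eef5303c54bc816b10367585402ab80fa3dfde2d294cc34b058f9d8d17a93
consensus_VEL1_NV.bed	f46a498f5fe3a049a21b3e712c8f4472611577e0ad2e95d0766866b197fd0f5a
consensus_VIN3_6WT0.bed	f20eb85bc6a8cb11add623fe4071259403fb528c882d06e5a300d20b165474ef
consensus_VIN3_NV.bed	4b6eaeb83c4b12952e0fa0fa29a978ed6f98b7e780b77e2fcc5bb73e6cd18a83
cooccupancy_6WT0.tsv	0da666d5446cd901edc6df928d1fc27f4322017b3ce00210c0c11fb06672795e
cooccupancy_NV.tsv	53ac573dbc1c4f40187aff20b806effb815f1941dd40192479b0332584a29aed
filtered_VEL1_6WT0_rep1.narrowPeak	9bb73cdcbc35e0189a66b3211e9c41599b8af07559cdea6da3daca08aa6a8640
filtered_VEL1_6WT0_rep2.narrowPeak	91392afddf4b8f45488048a43bb0d3b89565c204648337212fe9325adfa42154
filtered_VEL1_6WT0_rep3.narrowPeak	e303914ca0bf9c5c4083f327d9b6baba1cdd52fd6beaec30d39c19cc13edc469
filtered_VEL1_NV_rep1.narrowPeak	0e5afb1bd4373384b5d4e4ded3f6eb20c82ed673ac212a96e7677e526539aee7
filtered_VEL1_NV_rep2.narrowPeak	5256ae382670d49203ecf5403bf0bcce5e8735ed58b0456073f0834fc20975c2
filtered_VEL1_NV_rep3.narrowPeak	e7e536396fbdf480ee35b3d8efaed915b988d140a77cc3050ae67fa6c99b5627
filtered_VIN3_6WT0_rep1.narrowPeak	004aa1747d6e3d644594e0b85ee71ac5a5e69a8e6bc1b4be12ce24d8821e471f
filtered_VIN3_6WT0_rep2.narrowPeak	89d5d22aaf9210c75e5fb1ec29bbaf2f5f4f889b4fa4031875c77a9b1b8cb529
filtered_VIN3_6WT0_rep3.narrowPeak	f22ba2b422b6a1b808b9eb597a613a10661238e70a37f725d6ee3e687a0b5a90
filtered_VIN3_NV_rep1.narrowPeak	6812a110099376099f47822cba6f485c7ccea1018d05431127adb7aab3ec618b
filtered_VIN3_NV_rep2.narrowPeak	7afd630a5209aafb351695fe762f08b02ad93d74a4fb7732d4ecb85767629b57
filtered_VIN3_NV_rep3.narrowPeak	266ce372c8c5cb11bd91f01b913164945d464ef1d4b66fdd977cbe12b76132a8
manifest.json	5f16211a1b6811b487c744a46193d86f1cc0402cd4f226f9a153f21b3f6b61d4
metagene_VEL1_6WT0.tsv	0a56e9af3df6a870d314278a8d91ce37150c2ca86f6dd4effde24cdd3de95475
metagene_VEL1_NV.tsv	01a8ae9d697eb0bac671ce56280696bfb028f7f4b086c543f954f0912f5e8371
metagene_VIN3_6WT0.tsv	976ace6ce9c70337f36a4cd98a971019a6fee91cfa8b247e2364d55620367093
metagene_VIN3_NV.tsv	6012545938f24a2249963c66c26bd5ddbbbc4e12d0fc431ff646b9d796f5fc32
overlap_matrix_6WT0.tsv	1ea32d6a80c6e4dc8a323ee77dfccc8b47fa8a9f3ec35e8b63c1e7763958349e
overlap_matrix_NV.tsv	c0afd5eec024e8de7904a96baff4c8f12029de2328c281daac778c700beaa677
target_gene_table.tsv	157bf94921bd8b8379ac5cfe1e26e975c09aa6aa2efe5dbb7a5b88ab9aa82736
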