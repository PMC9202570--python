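iccc_subgroup,histology_spec,site_spec,behavior_spec
011,8000-8009,C00.0-C00.9,3
011,8010-8019,C01.0-C01.9,1;3
012,8040-8049,C02.0-C02.9,3
012,8050-8059,C03.0-C03.9,1;3
013,8080-8089,C04.0-C04.9,3
013,8090-8099,C05.0-C05.9,1;3
014,8120-8129,C06.0-C06.9,3
014,8130-8139,C07.0-C07.9,1;3
015,8160-8169,C08.0-C08.9,3
015,8170-8179,C09.0-C09.9,1;3
021,8200-8209,C10.0-C10.9,3
021,8210-8219,C11.0-C11.9,1;3
022,8240-8249,C12.0-C12.9,3
022,8250-8259,C13.0-C13.9,1;3
023,8280-8289,C14.0-C14.9,3
023,8290-8299,C15.0-C15.9,1;3
024,8320-8329,C16.0-C16.9,3
024,8330-8339,C17.0-C17.9,1;3
025,8360-8369,C18.0-C18.9,3
025,8370-8379,C19.0-C19.9,1;3
031,8400-8409,C20.0-C20.9,3
031,8410-8419,C21.0-C21.9,1;3
032,8440-8449,C22.0-C22.9,3
032,8450-8459,C23.0-C23.9,1;3
033,8480-8489,C24.0-C24.9,3
033,8490-8499,C25.0-C25.9,1;3
034,8520-8529,C26.0-C26.9,3
034,8530-8539,C27.0-C27.9,1;3
035,8560-8569,C28.0-C28.9,3
035,8570-8579,C29.0-C29.9,1;3
036,8600-8609,C30.0-C30.9,3
036,8610-8619,C31.0-C31.9,1;3
041,8640-8649,C32.0-C32.9,3
041,8650-8659,C33.0-C33.9,1;3
042,8680-8689,C34.0-C34.9,3
042,8690-8699,C35.0-C35.9,1;3
050,8720-8729,C36.0-C36.9,3
050,8730-8739,C37.0-C37.9,1;3
061,8760-8769,C38.0-C38.9,3
061,8770-8779,C39.0-C39.9,1;3
062,8800-8809,C40.0-C40.9,3
062,8810-8819,C41.0-C41.9,1;3
071,8840-8849,C42.0-C42.9,3
071,8850-8859,C43.0-C43.9,1;3
072,8880-8889,C44.0-C44.9,3
072,8890-8899,C45.0-C45.9,1;3
081,8920-8929,C46.0-C46.9,3
081,8930-8939,C47.0-C47.9,1;3
082,8960-8969,C48.0-C48.9,3
082,8970-8979,C49.0-C49.9,1;3
083,9000-9009,C50.0-C50.9,3
083,9010-9019,C51.0-C51.9,1;3
084,9040-9049,C52.0-C52.9,3
084,9050-9059,C53.0-C53.9,1;3
085,9080-9089,C54.0-C54.9,3
085,9090-9099,C55.0-C55.9,1;3
091,9120-9129,C56.0-C56.9,3
091,9130-9139,C57.0-C57.9,1;3
092,9160-9169,C58.0-C58.9,3
092,9170-9179,C59.0-C59.9,1;3
093,9200-9209,C60.0-C60.9,3
093,9210-9219,C61.0-C61.9,1;3
094,9240-9249,C62.0-C62.9,3
094,9250-9259,C63.0-C63.9,1;3
095,9280-9289,C64.0-C64.9,3
095,9290-9299,C65.0-C65.9,1;3
101,9320-9329,C66.0-C66.9,3
101,9330-9339,C67.0-C67.9,1;3
102,9360-9369,C68.0-C68.9,3
102,9370-9379,C69.0-C69.9,1;3
103,9400-9409,C00.0-C00.9,3
103,9410-9419,C01.0-C01.9,1;3
104,9440-9449,C02.0-C02.9,3
104,9450-9459,C03.0-C03.9,1;3
105,9480-9489,C04.0-C04.9,3
105,9490-9499,C05.0-C05.9,1;3
111,9520-9529,C06.0-C06.9,3
111,9530-9539,C07.0-C07.9,1;3
112,9560-9569,C08.0-C08.9,3
112,9570-9579,C09.0-C09.9,1;3
113,9600-9609,C10.0-C10.9,3
113,9610-9619,C11.0-C11.9,1;3
114,9640-9649,C12.0-C12.9,3
114,9650-9659,C13.0-C13.9,1;3
115,9680-9689,C14.0-C14.9,3
115,9690-9699,C15.0-C15.9,1;3
116,9720-9729,C16.0-C16.9,3
116,9730-9739,C17.0-C17.9,1;3
121,9760-9769,C18.0-C18.9,3
121,9770-9779,C19.0-C19.9,1;3
122,9800-9809,C20.0-C20.9,3
122,9810-9819,C21.0-C21.9,1;3
999,9840-9849,C22.0-C22.9,3
999,9850-9859,C23.0-C23.9,1;3
081,9180-9187,C40.0-C41.9,3
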