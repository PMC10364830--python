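label	state	self_est	self_lo	self_hi	corrected_est	corrected_lo	corrected_hi	men_est	men_lo	men_hi	women_est	women_lo	women_hi	sig_above_national
Alabama	AL	7.4	6.5	8.5	12.7	11.5	14.0	8.2	6.8	9.9	16.9	15.1	18.9	1
Alaska	AK	4.9	3.8	6.3	9.2	7.7	11.1	7.8	5.8	10.4	10.9	8.7	13.7	0
Arizona	AZ	4.6	4.0	5.3	7.8	7.0	8.6	5.8	4.9	6.9	9.8	8.5	11.2	0
Arkansas	AR	6.5	5.5	7.6	11.8	10.5	13.2	7.6	6.1	9.4	16.1	14.0	18.4	1
California	CA	4.6	3.8	5.7	8.0	6.7	9.4	6.4	4.9	8.4	9.5	7.8	11.6	0
Colorado	CO	3.3	2.9	3.8	5.7	5.2	6.3	3.8	3.2	4.5	7.7	6.8	8.8	0
Connecticut	CT	4.5	3.8	5.3	7.3	6.4	8.3	5.5	4.5	6.9	9.0	7.6	10.7	0
Delaware	DE	6.5	5.4	7.8	10.2	8.9	11.8	8.2	6.4	10.5	12.1	10.2	14.3	1
District of Columbia	DC	4.0	3.1	5.2	7.1	5.9	8.6	3.9	2.6	5.8	10.1	8.1	12.5	0
Florida	FL	4.5	3.7	5.5	6.9	5.9	8.0	5.1	4.1	6.4	8.7	7.1	10.6	0
Georgia	GA	6.4	5.5	7.4	10.2	9.1	11.4	8.5	6.9	10.4	11.9	10.4	13.5	1
Hawaii	HI	3.5	2.9	4.1	6.1	5.4	6.9	5.3	4.3	6.4	6.9	5.9	8.1	0
Idaho	ID	4.4	3.7	5.2	8.1	7.1	9.2	6.4	5.2	7.8	9.9	8.3	11.7	0
Illinois	IL	4.7	3.7	5.8	8.8	7.4	10.4	6.5	5.1	8.4	11.0	8.8	13.6	0
Indiana	IN	6.9	6.2	7.7	11.2	10.4	12.2	8.7	7.6	9.9	13.9	12.5	15.4	1
Iowa	IA	6.4	5.8	7.0	10.6	9.8	11.4	7.7	6.8	8.7	13.7	12.4	15.0	1
Kansas	KS	5.6	5.1	6.2	9.7	9.0	10.5	6.8	5.9	7.7	12.8	11.6	14.1	1
Kentucky	KY	7.8	6.7	9.0	11.8	10.4	13.4	8.4	7.0	10.2	15.2	13.1	17.6	1
Louisiana	LA	7.2	6.2	8.3	12.4	11.0	13.8	8.5	6.8	10.5	16.1	14.2	18.3	1
Maine	ME	5.1	4.4	5.9	8.3	7.5	9.3	6.8	5.8	8.1	9.9	8.6	11.3	0
Maryland	MD	4.9	4.4	5.5	8.0	7.4	8.8	5.5	4.7	6.5	10.6	9.5	11.7	0
Massachusetts	MA	3.3	2.7	4.0	5.5	4.8	6.3	4.3	3.4	5.3	6.8	5.6	8.2	0
Michigan	MI	6.5	5.8	7.3	10.8	9.9	11.9	7.6	6.4	8.9	14.2	12.6	15.9	1
Minnesota	MN	4.5	4.1	5.0	7.8	7.3	8.4	6.4	5.7	7.2	9.4	8.6	10.3	0
Mississippi	MS	7.8	7.0	8.7	13.0	11.9	14.1	8.3	7.0	9.8	17.4	15.8	19.1	1
Missouri	MO	6.6	5.9	7.3	10.4	9.6	11.3	7.2	6.2	8.4	13.7	12.4	15.2	1
Montana	MT	3.9	3.2	4.6	6.9	6.1	7.8	4.7	3.8	5.9	9.2	7.9	10.7	0
Nebraska	NE	5.2	4.7	5.8	8.8	8.1	9.5	5.9	5.1	6.7	11.8	10.6	13.1	0
Nevada	NV	5.0	4.0	6.3	8.1	6.8	9.7	6.5	4.9	8.6	9.7	7.7	12.2	0
New Hampshire	NH	5.0	4.2	5.9	7.9	7.0	9.0	6.0	4.8	7.5	10.0	8.5	11.6	0
New Jersey	NJ	3.8	3.4	4.4	6.5	5.8	7.2	5.4	4.6	6.3	7.6	6.6	8.7	0
New Mexico	NM	4.5	3.7	5.4	7.9	6.8	9.1	6.0	4.7	7.5	9.9	8.2	11.9	0
New York	NY	4.0	3.5	4.6	6.8	6.1	7.5	5.1	4.3	6.2	8.5	7.5	9.5	0
North Carolina	NC	5.2	4.4	6.1	9.0	8.0	10.1	6.8	5.5	8.3	11.2	9.8	12.9	0
North Dakota	ND	5.1	4.2	6.2	8.4	7.2	9.8	6.3	5.0	8.0	10.8	8.8	13.2	0
Ohio	OH	6.7	6.1	7.3	11.3	10.5	12.1	7.6	6.7	8.6	14.9	13.7	16.2	1
Oklahoma	OK	7.7	6.8	8.7	11.8	10.6	13.1	8.2	6.9	9.8	15.4	13.6	17.4	1
Oregon	OR	4.4	3.7	5.1	7.4	6.6	8.3	4.9	4.0	6.1	10.0	8.7	11.5	0
Pennsylvania	PA	5.3	4.5	6.1	8.5	7.5	9.6	6.5	5.3	8.0	10.6	9.1	12.2	0
Rhode Island	RI	3.8	3.1	4.7	7.1	6.1	8.3	4.9	3.6	6.5	9.4	7.8	11.2	0
South Carolina	SC	6.8	5.8	7.9	10.1	8.8	11.4	6.2	4.9	7.8	13.8	11.9	16.0	1
South Dakota	SD	4.8	4.0	5.9	7.8	6.6	9.2	6.4	5.0	8.1	9.4	7.3	12.0	0
Tennessee	TN	6.6	5.6	7.7	11.1	9.8	12.5	7.8	6.3	9.6	14.3	12.4	16.5	1
Texas	TX	5.4	4.7	6.4	9.4	8.3	10.6	7.1	5.7	8.8	11.8	10.2	13.6	0
Utah	UT	4.7	4.1	5.2	7.7	7.1	8.5	5.8	5.0	6.7	9.9	8.8	11.1	0
Vermont	VT	3.8	3.2	4.6	6.4	5.6	7.3	5.0	4.0	6.2	7.9	6.7	9.3	0
Virginia	VA	5.4	4.8	6.2	8.8	8.0	9.7	6.4	5.4	7.5	11.3	10.0	12.7	0
Washington	WA	4.4	3.9	4.9	7.2	6.6	7.9	5.4	4.7	6.3	9.1	8.2	10.2	0
West Virginia	WV	8.3	7.4	9.3	13.2	12.1	14.4	10.3	8.9	12.0	16.2	14.5	18.0	1
Wisconsin	WI	5.4	4.5	6.4	9.3	8.1	10.6	6.0	4.8	7.5	12.8	10.8	15.0	0
Wyoming	WY	3.6	2.8	4.4	6.9	5.8	8.2	4.8	3.6	6.2	9.4	7.6	11.6	0
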